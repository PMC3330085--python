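Place the public PDB entries 2RH1.pdb and 3SN6.pdb here to run the
structure-based acceptance checks; they are not redistributed with the package.
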