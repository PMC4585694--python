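>CaM_human mature human calmodulin, 148 residues
ADQLTEEQIAEFKEAFSLFDKDGDGTITTKELGTVMRSLGQNPTEAELQDMINEVDADGN
GTIDFPEFLTMMARKMKDTDSEEEIREAFRVFDKDGNGYISAAELRHVMTNLGEKLTDEE
VDEMIREADIDGDGQVNYEEFVQMMTAK
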