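# Synthetic stand-in for the TraI reference used for residue numbering.
# The 10 invariant AHL-synthase active-site residues are defined only in
# figure-level evidence in the source literature; their positions are left
# for the user to transcribe from Fuqua & Greenberg before use. The
# backbone sequence is a constructed (synthetic) sequence.
reference_id: TraI
sequence: |
  SNVFAAKLKWIHPTMWDVNLVQWEFMAKSIYIIPRSVVVQAITHTSGIPNIICTKNIVIM
  LDPFGGFPTAWPLGFMPFCERMCMWVGQTDWAWFLRNVTFMEIPIWLKTKIQARDKGNGS
  IVNKEWNPEILSIKQQILNSHDFPAGYINYRAKFLNCDSGVSFPESTAYIFLLNDNICKH
  VSMWEQHTKMTHRRCTKDQL
sites: []  # fill in: (position, expected, role: synthase_active) x 10
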