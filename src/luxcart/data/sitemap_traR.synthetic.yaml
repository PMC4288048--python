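# Synthetic stand-in for the TraR reference used for residue numbering.
# The site positions and expected residues follow the canonical TraR
# numbering of LuxR-family invariant sites; the backbone sequence is a
# constructed (synthetic) sequence carrying those residues at those
# positions, not the natural TraR protein.
reference_id: TraR
sequence: |
  RHTNYAGNFCSWPEDTAKDFYCCPCNDWFYSVWIQTHSIWCENQPNNSFRTFGHQDWIDW
  YTWKLVIWCDDYHKDPPIDQKIYNWRMIREFCDIQCWPMWRQDQTTQFMEANDQYSKFCF
  KSYFDFREPNHWWCDVQNDLAMALRWFKSFRPPGMDGVPHRKTHFLMFMTMHRLQEAEWY
  LLRNKAMGFDYARIRLNLTRHVLYELCGVLDHHVTHKQHFHSTRRMRPESWKPR
sites:
  - {position: 57, expected: W, role: autoinducer_binding}
  - {position: 61, expected: Y, role: autoinducer_binding}
  - {position: 70, expected: D, role: autoinducer_binding}
  - {position: 85, expected: W, role: autoinducer_binding}
  - {position: 178, expected: E, role: DNA_binding}
  - {position: 182, expected: L, role: DNA_binding}
  - {position: 188, expected: G, role: DNA_binding}
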