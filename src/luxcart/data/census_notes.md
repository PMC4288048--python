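# Packaged census fixture

`census_table.tsv` transcribes, row for row, the published per-genome census
of luxI/luxR circuit arrangements across 62 Sphingomonadaceae genomes (40 of
which carry at least one lux gene and therefore appear as rows).
`census_totals.tsv` carries the per-genus genome totals from the same survey's
genus headers.

The transcription is verbatim: internal inconsistencies present in the source
survey are preserved here and deliberately NOT reconciled:

- The survey's abstract claims the convergent double luxR-luxR-luxI
  arrangement in "13 Sphingobium and one Sphingomonas" genomes, but the table
  itself contains 11 Sphingobium and 2 Sphingomonas rows with a non-zero
  double count. The table's numbers are what this fixture carries.
- The abstract describes Sphingobium yanoikuyae B1 as containing seven ORFs
  with significant luxR homology; the table's B1 row (2 canonical, 0 double,
  0 luxI solo, 1 luxR solo) accounts for 3 luxR genes. The table row for
  S. yanoikuyae ATCC 51230 (2, 0, 1, 5 = 7 luxR genes) matches the "seven"
  figure; which strain was intended is not guessed.
- The abstract names three genomes "contained four luxI" (SYK6, S. japonicum,
  S. lactosutens); the table rows for these account for 3 luxI each
  (2 canonical + 1 double). Not reconciled.
- The survey's running text says 40/62 genomes contain at least one luxI OR
  luxR and 33 contain at least one canonical pair, while its abstract says 40
  contain at least one luxR and 33 at least one luxI. Both pairs of numbers
  are consistent with the table rows as transcribed; the roll-up code computes
  them from the rows rather than storing either claim.

Genus assignment comes from the fixture's own `genus` column, never from
parsing organism names.
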