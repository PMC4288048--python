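genus	n_genomes_total
Novosphingobium	11
Sphingobium	24
Sphingomonas	22
Sphingopyxis	5
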