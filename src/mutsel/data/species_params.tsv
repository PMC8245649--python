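name	ne	mode	printed_u0	printed_u
Escherichia coli	4e8	haploid_asexual	4e-7	8.3e-4
Bacillus subtilis	6e7	haploid_asexual	6e-6	1.2e-3
Saccharomyces cerevisiae	1e7	diploid_asexual	5e-7	1.7e-3
Schizosaccharomyces pombe	1e7	haploid_asexual	1e-6	1.6e-3
Chlamydomonas reinhardtii	4e7	haploid_sexual	3.8e-5	3.8e-2
Arabidopsis thaliana	4e5	diploid_sexual	3.8e-3	2.9e-1
Drosophila melanogaster	1e6	diploid_sexual	1.5e-3	1.9e-1
Mus musculus	1e5	diploid_sexual	1.5e-2	7.0e-1
Homo sapiens	1e4	diploid_sexual	1.5e-1	2.9
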