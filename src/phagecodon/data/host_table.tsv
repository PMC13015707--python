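species	accession	genus
Escherichia coli K12	NC_000913.3	Escherichia
Shigella flexneri 2457T	NC_004741.1	Shigella
Salmonella enterica serovar Typhimurium SL1334	NC_016810.1	Salmonella
Salmonella enterica serovar Enteritidis 92-0392	NZ_CP018657.1	Salmonella
Mycobacterium smegmatis mc2 155	NC_008596.1	Mycobacterium
Bacillus subtilis 168	NC_000964.3	Bacillus
Bacillus cereus ATCC 14579	NZ_CP138336.1	Bacillus
Staphylococcus aureus NCTC 8325	NC_007795.1	Staphylococcus
Lactobacillus paracasei 8700:2	NC_022112.1	Lactobacillus
Lactobacillus brevis NCTC13768	NZ_LS483405.1	Lactobacillus
Lactobacillus plantarum WCFS1	NC_004567.1	Lactobacillus
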