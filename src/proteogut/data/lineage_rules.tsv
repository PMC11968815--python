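# Default lineage routing rules.
# Columns: taxid, parent_taxid (0 = none/root), domain, table_id ('-' for Host).
# Taxids without an exact rule are resolved by walking parent links to the
# nearest ancestor that has one; anything unresolvable routes as Unknown
# (bacteria-default tools, translation table 11).
131567	0	Bacteria	11
2	131567	Bacteria	11
2157	131567	Archaea	11
2759	131567	Eukaryota	1
10239	0	Viruses	1
544448	2	Bacteria	4
2093	544448	Bacteria	4
2092	544448	Bacteria	4
33154	2759	Eukaryota	1
4751	33154	Eukaryota	1
9606	33154	Host	-
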