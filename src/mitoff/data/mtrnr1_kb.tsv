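# mitoff MT-RNR1 ototoxicity knowledge base, schema=1
# Variants in the mitochondrial 12S rRNA gene reported in connection with
# aminoglycoside-induced hearing loss. Positions are 1-based rCRS.
position	ref	alt	tier	note	pmid_refs
1555	A	G	strong	principal aminoglycoside-ototoxicity variant; near-complete penetrance on exposure	.
1494	C	T	strong	well-supported ototoxicity variant	.
669	T	C	needs_further_study	.	.
827	A	G	needs_further_study	most frequent further-study variant	.
896	A	G	needs_further_study	.	.
930	G	A	needs_further_study	.	.
961	T	C	needs_further_study	homopolymer caution: reference T flanked by cytosine runs; indel calls unreliable	.
961	T	G	needs_further_study	homopolymer caution: reference T flanked by cytosine runs; indel calls unreliable	.
988	G	A	needs_further_study	.	.
1005	T	C	needs_further_study	.	.
1048	C	T	needs_further_study	.	.
1189	T	C	needs_further_study	.	.
1243	T	C	needs_further_study	.	.
1438	G	A	needs_further_study	.	.
1462	G	A	needs_further_study	.	.
1537	C	T	needs_further_study	.	.
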