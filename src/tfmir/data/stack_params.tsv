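# Nearest-neighbor duplex parameters, kcal/mol at 37 C.
# Watson-Crick stack free energies are the published Xia et al. (1998)
# Turner-set values; G.U wobble stacks are representative mild values.
# A stack row "stack P Q dG" gives the energy of pair P (5' side, written
# top-strand base then bottom-strand base) stacked on pair Q; the symmetric
# partner stack(rev Q, rev P) is filled in automatically when absent.
init_penalty	4.09
bulge_open	3.80
bulge_extend	0.50
internal_open	4.00
internal_extend	0.40
allow_gu	true
max_loop	10
stack	AU	AU	-0.93
stack	AU	UA	-1.10
stack	UA	AU	-1.33
stack	CG	UA	-2.08
stack	CG	AU	-2.11
stack	GC	UA	-2.24
stack	GC	AU	-2.35
stack	CG	GC	-2.36
stack	GC	GC	-3.26
stack	GC	CG	-3.42
stack	GU	AU	-0.80
stack	GU	UA	-0.60
stack	GU	CG	-1.40
stack	GU	GC	-1.30
stack	GU	GU	-0.50
stack	GU	UG	-0.30
stack	UG	AU	-0.70
stack	UG	UA	-0.60
stack	UG	CG	-1.20
stack	UG	GC	-1.50
stack	UG	UG	-0.50
stack	UG	GU	-0.40
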