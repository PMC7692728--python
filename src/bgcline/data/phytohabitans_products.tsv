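strain	cluster_id	deduced_product	kind
flavus	t1pks-1	enediyne-compounds	prose
rumicis	t1pks-1	enediyne-compounds	prose
houttuyneae	t1pks-1	enediyne-compounds	prose
suffuscus	t1pks-1	enediyne-compounds	prose
rumicis	t1pks-4	unknown	prose
houttuyneae	t1pks-4	unknown	prose
flavus	t3pks-1	alkyl-O-dihydrogeranyl-methoxyhydroquinones	name
rumicis	t3pks-1	alkyl-O-dihydrogeranyl-methoxyhydroquinones	name
houttuyneae	t3pks-1	alkyl-O-dihydrogeranyl-methoxyhydroquinones	name
suffuscus	t3pks-1	alkyl-O-dihydrogeranyl-methoxyhydroquinones	name
houttuyneae	t3pks-4	diazepinomicin	name
suffuscus	t3pks-4	diazepinomicin	name
flavus	nrps-2	s-x-Asn-Ser-x-Asn-Gly	chain
rumicis	nrps-2	s-x-Asn-Ser-x-Asn-Gly	chain
flavus	nrps-3	mHaOrn-x-mOrn-HaOrn-hOrn	chain
rumicis	nrps-3	mHaOrn-x-mOrn-HaOrn	chain
houttuyneae	nrps-3	mHaOrn-x-mOrn-HaOrn-hOrn	chain
suffuscus	nrps-3	mHaOrn-x-mOrn-HaOrn-hOrn	chain
rumicis	nrps-4	s-y-Asx	chain
houttuyneae	nrps-4	s-y-Asx	chain
houttuyneae	nrps-11	s-x-x-Thr-x-x-Orn-x-Ala-Asn	chain
suffuscus	nrps-11	s-x-x-Thr-x-x-Orn-x-Ala-Asn	chain
flavus	pks/nrps-3	large polyene	prose
houttuyneae	pks/nrps-3	large polyene	prose
suffuscus	pks/nrps-3	large polyene	prose
flavus	t1pks-2	large polyketide with anthracimycin-like moiety	prose
flavus	t1pks/t3pks	large polyene with a starter derived from type-III PKS	prose
flavus	nrps-1	s-x	chain
flavus	pks/nrps-1	AHBA-pk	chain
flavus	pks/nrps-2	s-x-pk-Asp-y-Dha-Dha	chain
rumicis	t1pks-3	pyrrolomycin	name
rumicis	t3pks-2	terpenoid with pk moiety	prose
rumicis	t3pks-3	unknown	prose
rumicis	nrps-5	x-y-Cys-x	chain
rumicis	nrps-6	Phe-x-Ser-x	chain
rumicis	nrps-7	x-Gly-Gly-x	chain
rumicis	pks/nrps-4	x-Phe-x-Phe-pk	chain
rumicis	pks/nrps-5	pk-Ser-x-Ser-Gly-x	chain
houttuyneae	t1pks-5	unknown	prose
houttuyneae	t1pks-6	deschlorothricin-like polyketide	prose
houttuyneae	t3pks-4b	unknown	prose
houttuyneae	nrps-8	x-x	chain
houttuyneae	nrps-9	x-x-dVal-dVal-x-dx-Thr-Val-x	chain
houttuyneae	nrps-10	pentapeptide containing Gly and Cys	prose
houttuyneae	nrps-12	Val-x-y-x-x	chain
houttuyneae	pks/nrps-6	Ala-Leu-x-pk	chain
houttuyneae	pks/nrps-7	x-Phe-Asp-Asp-x-Asp-x-Gly-Leu-Tyr-Thr-x-Asp-Gly-Asp-x-x-x-x-Thr-Tyr-Asp-Tyr-Asp with pk	prose
houttuyneae	pks/nrps-8	x-Gly-pk-Gly-x	chain
suffuscus	t1pks-7	polyene derived from C24 polyketide chain	prose
suffuscus	nrps-13	s-x-Leu-x-y-Ser	chain
suffuscus	nrps-14	cephamycin	name
suffuscus	nrps-15	DHB-Ser	chain
suffuscus	pks/nrps-9	hexapeptide including Ser, Cys, Pro, pk and enediyne-moiety	prose
suffuscus	pks/nrps-10	polyketide including a thiazoline residue	prose
suffuscus	pks/nrps-11	chlorizidine	name
suffuscus	pks/nrps-12	likely polyene with Leu	prose
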