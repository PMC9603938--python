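taxon	name	arm_id	status	kind	component_count	frequency	notes
S. ustulatum	IS-2	IS	fixed	inversion	1	1.00	named IS-1 in the running text; table spelling is canonical
S. ustulatum	IL us-1	IL	polymorphic	inversion	1	0.58	in HWE in the focal sample
S. ustulatum	IIS-1	IIS	fixed	inversion	1	1.00	Y-linked where it occurs in S. quadratum
S. ustulatum	IIL-1	IIL	fixed	inversion	1	1.00	shared with several group members
S. ustulatum	IIL-2	IIL	fixed	inversion	1	1.00	subterminal simple inversion
S. ustulatum	IIL eu, us-1	IIL	fixed	inversion	1	1.00	equivalent to IIL-3; a polymorphism in S. annulus (IIL eu-1)
S. ustulatum	IIL-complex	IIL	fixed	inversion	4	1.00	four overlapping fixed inversions
S. ustulatum	IIL us-1	IIL	polymorphic	inversion	1	0.10
S. ustulatum	IIL us-2	IIL	polymorphic	inversion	1	0.74
S. ustulatum	IIIL-1	IIIL	fixed	inversion	1	1.00	equivalent to IIIL eu-5, a polymorphism in S. annulus
S. ustulatum	IIIL-2	IIIL	fixed	inversion	1	1.00	mimic of IIIL ca, eu, em, Hi, us-1
S. ustulatum	IIIL ca, eu, em, Hi, us-1	IIIL	polymorphic	inversion	1	0.71	shared with numerous group members
S. ustulatum	IIIL N.O. transposition	IIIL	fixed	transposition	1	1.00	nucleolar organizer transposed within section 84
S. ustulatum	IIIL N.O.	IIIL	sex_linked_marker	nucleolar_expression	1		anucleolate Y: X nucleolate, Y anucleolate
S. annulus	IIIL N.O.	IIIL	sex_linked_marker	nucleolar_expression	1		anucleolate Y
S. annulus	IIL-1	IIL	fixed	inversion	1	1.00
S. annulus	IIL eu-1	IIL	polymorphic	inversion	1		autosomal polymorphism; same inversion as IIL eu, us-1
S. annulus	IIIL eu-5	IIIL	polymorphic	inversion	1		autosomal polymorphism; same inversion as IIIL-1
S. annulus	IIIL ca, eu, em, Hi, us-1	IIIL	polymorphic	inversion	1
S. annulus	IIIL-2	IIIL	polymorphic	inversion	1		Y-linked in some eastern populations
S. quadratum	IIS-1	IIS	polymorphic	inversion	1		Y-linked
S. quadratum	IIL-1	IIL	fixed	inversion	1	1.00
S. quadratum	IIIL eu-5	IIIL	polymorphic	inversion	1
S. quadratum	IIIL-2	IIIL	polymorphic	inversion	1
S. balteatum	IIIL N.O.	IIIL	sex_linked_marker	nucleolar_expression	1		anucleolate Y
S. balteatum	IIL-1	IIL	fixed	inversion	1	1.00
S. balteatum	IIIL-2	IIIL	polymorphic	inversion	1
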