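name	formula	half_reaction	ne_override	role
formic acid	CH2O2			donor_or_product
acetic acid	C2H4O2			product
propionic acid	C3H6O2			product
butyric acid	C4H8O2			product
isobutyric acid	C4H8O2			product
lactic acid	C3H6O3			product
succinic acid	C4H6O4			product
4-methylvaleric acid	C6H12O2			product
hydrogen		H2_to_protons	2	donor_or_product
thiosulfate		thiosulfate_to_sulfate	8	donor
sulfate		terminal_acceptor	0	acceptor
Fe(III)		ferric_to_ferrous	1	acceptor
nitrate		terminal_acceptor	0	acceptor
nitrite		terminal_acceptor	0	acceptor
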