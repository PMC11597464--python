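name	formula	mass
glucosyl	C6H10O5	162.0528
glucuronosyl	C6H8O6	176.0321
pentosyl	C5H8O4	132.0423
malonyl	C3H2O3	86.0004
hydroxymethylglutaryl	C6H8O4	144.0423
feruloyl	C10H8O3	176.0473
coumaroyl	C9H6O2	146.0368
sulfo	SO3	79.9568
carboxyl	CO2	43.9898
dehydrogenation	H2	2.0157
water	H2O	18.0106
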