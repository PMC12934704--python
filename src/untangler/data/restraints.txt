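# Restraint dictionary: bead-peptide fixtures, water, and a
# reduced amino-acid set (backbone + CB).  Format:
#   template <resname> / link headers, then one record per term:
#   <category> <atom names...> <v0> <sigma> [periodicity]
#   '+NAME' refers to the next residue in the chain.

template BEA
bond N CA 1.470 0.020
bond CA C 1.530 0.020
bond CA CB 1.530 0.020
angle N CA C 111.0 2.0
angle N CA CB 110.0 2.0
torsion C N CA CB -120.0 10.0

template HOH
bond O H1 0.960 0.020
bond O H2 0.960 0.020
angle H1 O H2 104.5 2.5

template ALA
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template ARG
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template ASN
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template ASP
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template CYS
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template GLN
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template GLU
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template GLY
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template HIS
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template ILE
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template LEU
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template LYS
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template MET
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template PHE
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template PRO
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template SER
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template THR
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template TRP
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template TYR
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

template VAL
bond N CA 1.458 0.019
bond CA C 1.525 0.021
bond C O 1.231 0.020
bond C OXT 1.249 0.019
bond CA CB 1.530 0.020
angle N CA CB 110.4 2.0
angle N CA C 111.2 2.8
angle CA C O 120.8 1.7

link
bond C +N 1.330 0.020
angle CA C +N 116.0 2.0
angle C +N +CA 122.0 2.0
omega CA C +N +CA 180.0 5.0 1
torsion N CA C +N 150.0 20.0
torsion C +N +CA +C -140.0 20.0

vdw C 1.60
vdw N 1.50
vdw O 1.45
vdw S 1.80
vdw H 1.00
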