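# glycotree residue template, format v1
# residue: beta-D-GlcNAc
# anomeric: beta
# columns: name element bond_ref length(A) angle_ref angle(deg) torsion_ref torsion(deg)
O5   O  -    - -    - -    -
C1   C  O5   1.430000 -    - -    -
C2   C  C1   1.530000 O5   117.971257 -    -
C3   C  C2   1.530000 C1   104.365094 O5   58.278959
C4   C  C3   1.530000 C2   110.593702 C1   -51.696992
C5   C  O5   1.430000 C1   109.980486 C2   -61.670396
O1   O  C1   1.430000 O5   109.470000 C2   -126.017875
H1   H  C1   1.090000 O5   109.470000 C2   126.017875
N2   N  C2   1.470000 C1   109.470000 O5   175.374835
H2   H  C2   1.090000 C1   109.470000 O5   -58.816917
O3   O  C3   1.430000 C2   109.470000 C1   -172.394223
H3   H  C3   1.090000 C2   109.470000 C1   69.000240
O4   O  C4   1.430000 C3   109.470000 C2   177.529668
H4   H  C4   1.090000 C3   109.470000 C2   -67.315958
C6   C  C5   1.530000 O5   109.470000 C1   175.316069
H5   H  C5   1.090000 O5   109.470000 C1   -65.150495
O6   O  C6   1.430000 C5   109.470000 O5   -60.000000
H6A  H  C6   1.090000 C5   109.470000 O5   -179.997010
H6B  H  C6   1.090000 C5   109.470000 O5   59.997010
HO1  H  O1   0.960000 C1   109.470000 O5   -49.259643
HO3  H  O3   0.960000 C3   109.470000 C2   180.000000
HO4  H  O4   0.960000 C4   109.470000 C3   180.000000
HO6  H  O6   0.960000 C6   109.470000 C5   180.000000
C7   C  N2   1.350000 C2   120.000000 C1   120.000000
HN2  H  N2   1.010000 C2   120.000000 C1   -60.000000
O7   O  C7   1.220000 N2   120.000000 C2   0.000000
C8   C  C7   1.530000 N2   120.000000 C2   180.000000
H81  H  C8   1.090000 C7   109.470000 N2   60.000000
H82  H  C8   1.090000 C7   109.470000 N2   180.000000
H83  H  C8   1.090000 C7   109.470000 N2   -60.000000
# closure: C4-C5
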