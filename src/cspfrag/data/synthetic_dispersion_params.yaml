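# SYNTHETIC dispersion parameter set for testing the pair-dispersion engine.
# These are NOT fitted physical constants: the reference C6 values, Q factors
# and damping vector are invented so that the interpolation, recursion and
# damping code paths can be exercised with closed-form expectations.  C6 in
# (kJ/mol)·Å^6, C8 consequently in (kJ/mol)·Å^8, radii in Å.
cn_constants:
  k1: 16.0
  k2: 1.3333333333333333
  k3: 4.0
q_factors:
  H: 2.0
  C: 6.0
  N: 5.0
  O: 4.0
  Ne: 3.0
  Ar: 8.0
covalent_radii: {}
damping:
  family: tang-toennies
  params:
    b: 2.5
    s6: 1.0
    s8: 0.75
reference_table:
  cks:
    H-H:
      - [0.0, 0.0, 8.0]
      - [1.0, 1.0, 6.5]
    C-H:
      - [0.0, 0.0, 22.0]
      - [4.0, 1.0, 18.0]
    C-C:
      - [0.0, 0.0, 60.0]
      - [4.0, 4.0, 48.0]
    Ne-Ne:
      - [0.0, 0.0, 12.0]
    Ar-Ar:
      - [0.0, 0.0, 64.0]
    Ar-Ne:
      - [0.0, 0.0, 27.0]
    H-Ne: [[0.0, 0.0, 9.0]]
    H-Ar: [[0.0, 0.0, 21.0]]
    C-Ne: [[0.0, 0.0, 25.0]]
    C-Ar: [[0.0, 0.0, 58.0]]
    N-N: [[0.0, 0.0, 50.0], [3.0, 3.0, 42.0]]
    N-H: [[0.0, 0.0, 19.0]]
    C-N: [[0.0, 0.0, 54.0]]
    N-Ne: [[0.0, 0.0, 23.0]]
    N-Ar: [[0.0, 0.0, 52.0]]
    O-O: [[0.0, 0.0, 40.0], [2.0, 2.0, 34.0]]
    O-H: [[0.0, 0.0, 16.0]]
    C-O: [[0.0, 0.0, 47.0]]
    N-O: [[0.0, 0.0, 44.0]]
    Ne-O: [[0.0, 0.0, 20.0]]
    Ar-O: [[0.0, 0.0, 46.0]]
  uchf:
    H-H:
      - [0.0, 0.0, 10.0]
      - [1.0, 1.0, 8.0]
    C-H:
      - [0.0, 0.0, 26.0]
      - [4.0, 1.0, 21.0]
    C-C:
      - [0.0, 0.0, 72.0]
      - [4.0, 4.0, 57.0]
    Ne-Ne:
      - [0.0, 0.0, 15.0]
    Ar-Ar:
      - [0.0, 0.0, 80.0]
    Ar-Ne:
      - [0.0, 0.0, 34.0]
    H-Ne: [[0.0, 0.0, 11.5]]
    H-Ar: [[0.0, 0.0, 26.0]]
    C-Ne: [[0.0, 0.0, 31.0]]
    C-Ar: [[0.0, 0.0, 70.0]]
    N-N: [[0.0, 0.0, 61.0], [3.0, 3.0, 51.0]]
    N-H: [[0.0, 0.0, 23.0]]
    C-N: [[0.0, 0.0, 65.0]]
    N-Ne: [[0.0, 0.0, 28.0]]
    N-Ar: [[0.0, 0.0, 63.0]]
    O-O: [[0.0, 0.0, 49.0], [2.0, 2.0, 41.0]]
    O-H: [[0.0, 0.0, 19.5]]
    C-O: [[0.0, 0.0, 57.0]]
    N-O: [[0.0, 0.0, 54.0]]
    Ne-O: [[0.0, 0.0, 24.5]]
    Ar-O: [[0.0, 0.0, 56.0]]
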