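"""Built-in Gaussian basis-set data.

STO-3G exponents and contraction coefficients (Hehre, Stewart & Pople).
The s and p members of an sp shell share exponents; contraction
coefficients are the row-universal STO-3G values.  Covers every element
the packaged solute/solvent templates and fixtures can produce.
"""

# Per element: list of shells, each shell = (angular momentum l, exponents, coefficients)
STO3G = {
    "H": [
        (0, [3.425250914, 0.6239137298, 0.1688554040],
            [0.1543289673, 0.5353281423, 0.4446345422]),
    ],
    "He": [
        (0, [6.362421394, 1.158922999, 0.3136497915],
            [0.1543289673, 0.5353281423, 0.4446345422]),
    ],
    "C": [
        (0, [71.61683735, 13.04509632, 3.530512160],
            [0.1543289673, 0.5353281423, 0.4446345422]),
        (0, [2.941249355, 0.6834830964, 0.2222899159],
            [-0.09996722919, 0.3995128261, 0.7001154689]),
        (1, [2.941249355, 0.6834830964, 0.2222899159],
            [0.1559162750, 0.6076837186, 0.3919573931]),
    ],
    "N": [
        (0, [99.10616896, 18.05231239, 4.885660238],
            [0.1543289673, 0.5353281423, 0.4446345422]),
        (0, [3.780455879, 0.8784966449, 0.2857143744],
            [-0.09996722919, 0.3995128261, 0.7001154689]),
        (1, [3.780455879, 0.8784966449, 0.2857143744],
            [0.1559162750, 0.6076837186, 0.3919573931]),
    ],
    "O": [
        (0, [130.7093214, 23.80886605, 6.443608313],
            [0.1543289673, 0.5353281423, 0.4446345422]),
        (0, [5.033151319, 1.169596125, 0.3803889600],
            [-0.09996722919, 0.3995128261, 0.7001154689]),
        (1, [5.033151319, 1.169596125, 0.3803889600],
            [0.1559162750, 0.6076837186, 0.3919573931]),
    ],
    "F": [
        (0, [166.6791340, 30.36081233, 8.216820672],
            [0.1543289673, 0.5353281423, 0.4446345422]),
        (0, [6.464803249, 1.502281245, 0.4885884864],
            [-0.09996722919, 0.3995128261, 0.7001154689]),
        (1, [6.464803249, 1.502281245, 0.4885884864],
            [0.1559162750, 0.6076837186, 0.3919573931]),
    ],
    "Na": [
        (0, [250.7724300, 45.67851117, 12.36238776],
            [0.1543289673, 0.5353281423, 0.4446345422]),
        (0, [12.04019274, 2.797881859, 0.7494474603],
            [-0.09996722919, 0.3995128261, 0.7001154689]),
        (1, [12.04019274, 2.797881859, 0.7494474603],
            [0.1559162750, 0.6076837186, 0.3919573931]),
        (0, [1.478740622, 0.4125648801, 0.1614750979],
            [-0.2196203690, 0.2255954336, 0.9003984260]),
        (1, [1.478740622, 0.4125648801, 0.1614750979],
            [0.01058760429, 0.5951670053, 0.4620010120]),
    ],
}

BASIS_SETS = {"sto-3g": STO3G}
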