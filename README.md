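# molclas

Information-entropy classification of small molecules from ranked binary
structural fingerprints, with the companion analyses used to validate such
classifications: correlation PCA, QSPR retention regressions, and a
"periodic table" layout of compounds.

The package ships a nine-pesticide LC–MS–MS benchmark set (methamidophos,
carbendazim, thiabendazole, pyrimethanil, cyprodinil, the internal standard
triphenyl phosphate, diazinone, pyrazophos, chlorpyrifos) whose published
classification, PCA, regression and periodic-table results it reproduces
end to end. It is aimed at cheminformatics practitioners who want a small,
transparent, fully testable implementation of the method rather than a
black-box clustering tool.

## The method

Each compound is encoded as an ordered binary *property vector*
⟨i₁…i₆⟩ — presence of 1–3 rings, 0 or 3–5 oxygens, nonplanarity, a
thiono (double-bonded) sulphur, 1 or 3 nitrogens, exactly 3 chlorines —
ranked by expected importance for chromatographic retention. Similarity
between two compounds is

    r_ij = Σₖ tₖ aₖᵏ,   tₖ = 1 if the vectors agree at position k,

so a match at rank k is worth aₖᵏ (default aₖ = 0.5: 0.5, 0.25, …).
The raw matrix **R** is *stabilized* by iterating the max–min composition
(**R**∘**R**)ᵢⱼ = maxₖ min(rᵢₖ, rₖⱼ) to a fixed point, which makes the
relation rᵢⱼ(n) ≥ b an equivalence for any grouping level b. Each
partition is scored by the information entropy of its class matrix,

    h = Σ over all N² entries of −x ln x − (1−x) ln(1−x),

and scanning b gives an entropy-vs-level staircase. Among candidate
weight schemes, the *equipartition conjecture* prefers the one whose
staircase is closest (least squared deviation) to the line h = h_max·b;
a seeded stochastic hill climb (`learn_weights`) fits weights toward a
reference matrix under a symmetrized Kullback–Leibler distance.

Reading the vector as a decimal number, P = 10⁵i₁ + … + 10i₅ + i₆,
places each compound in a periodic table (groups = ⟨i₁…i₅⟩, periods =
⟨i₆⟩); the successive differences D(p) and ratios R(p) of P along the
table probe how regular the layout is. Retention is modelled by OLS on
log P and the molecular fractal dimensions D, D′ (external inputs).

## Worked example

```sh
$ molclas classify --levels 0.93,0.76
b       classes h
0.93    5       10.70
0.76    3       3.71
...
C-0.93  (Methamidophos)(Carbendazim)(Thiabendazole,Pyrimethanil,Cyprodinil)(TPP)(Diazinone,Pyrazophos,Chlorpyrifos)
C-0.76  (Methamidophos)(Carbendazim)(Thiabendazole,Pyrimethanil,Cyprodinil,TPP,Diazinone,Pyrazophos,Chlorpyrifos)
```

At b = 0.93 the nine pesticides fall into five classes with entropy
10.70 nat: the three planar anilinopyrimidine/benzimidazole fungicides
group together, as do the three nonplanar thiophosphates with the longest
retention. Relaxing to b = 0.76 merges everything but the two least
retained compounds. The same library calls are available in Python:

```python
from molclas import load_table1, similarity_matrix, level_scan, fit_model

records = load_table1()
raw = similarity_matrix([r.vector for r in records])
profile = level_scan(raw)          # entropy staircase over all merge levels
eq1 = fit_model(records, "eq1")    # retention ~ logP + (D' - D)
print(f"r = {eq1.r:.3f}, s = {eq1.s:.3f}, F = {eq1.F:.1f}")
# r = 0.973, s = 0.337, F = 53.3
```

`molclas demo` prints the full benchmark reproduction: the eight-level
entropy scan (32.49 … 0.08), the similarity-diagram bin counts
(21 high / 7 medium / 1 low / 7 zero), the PCA eigenvalue table
(F₁ = 2.33109829, 86.93 % cumulative variance at three factors), the five
retention models, and the periodic-table placements with the P/D/R series.

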