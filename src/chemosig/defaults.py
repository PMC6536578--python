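"""Single home for every deliberately chosen analysis default.

All thresholds that shape the scientific output live here, never scattered
through the code, so a run report plus this module fully determines a result.

* ``K_SIGNATURE`` / ``R_MIN`` — signature selection keeps up to 20 genes per
  direction with Pearson |r| at or beyond 0.50.
* ``K_CLUSTERS`` — the dendrogram over cell lines is cut into 4 clusters.
* ``RESISTANCE_LOWER`` / ``RESISTANCE_UPPER`` — a derivative/parental IC50
  ratio at or below 0.5 is called collateral-sensitive, at or above 2.0
  cross-resistant, otherwise unchanged.
* ``MEDIAN_TIE_RULE`` — cell lines exactly at the median log10(IC50) are
  labelled resistant (the ``>=`` rule); ``"sensitive"`` flips them.
* ``MC_MIN_EXPECTED`` / ``MC_REPS`` — a Monte-Carlo p-value is added to the
  chi-square predictability test whenever any expected cell count falls
  below 5, using 10000 fixed-margin permutations by default.
"""

K_SIGNATURE: int = 20
R_MIN: float = 0.50

K_CLUSTERS: int = 4

RESISTANCE_LOWER: float = 0.5
RESISTANCE_UPPER: float = 2.0

MEDIAN_TIE_RULE: str = "resistant"

MC_MIN_EXPECTED: float = 5.0
MC_REPS: int = 10000
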