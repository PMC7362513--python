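"""IHC scoring primitives: H-score, strata, densities.

Builds a few hand-sized measurements and prints the derived scores.
"""

from cafkit import (
    FieldMeasurement,
    IntensityHistogram,
    adiposity_score,
    cell_density,
    compute_h_score,
    dichotomize_by_median,
    stratify_3cat,
    vessel_fraction,
)

# A tumor where 20% of fibroblasts are unstained, 30% weak, 40%
# moderate and 10% strong: H = 0*20 + 1*30 + 2*40 + 3*10 = 140.
hist = IntensityHistogram({0: 20, 1: 30, 2: 40, 3: 10})
h = compute_h_score(hist)
print(f"H-score: {float(h):.0f}  (range 0-300; percent stained x intensity 0-3)")

# Median dichotomization of a small cohort of FAP H-scores.
fap = [10, 47, 48, 96, 120, 30]
labels, med = dichotomize_by_median(fap)
print(f"median FAP H-score {med:.1f} -> labels {labels}")

# Three-category FAP strata (low <= 47 < intermediate <= 95 < high).
print("FAP strata:", dict(zip(fap, stratify_3cat(fap))))

# CD4+ T-cell density: 33 cells over three x10 fields of 1.65 mm^2.
fields = [FieldMeasurement(field_area=1.65)] * 3
print(f"CD4 density: {cell_density(33, fields):.2f} cells/mm^2")

# CD31 vessel fraction normalized on stromal content, mean over fields.
print(f"vessel fraction: {vessel_fraction([(2.0, 50.0)] * 8):.2f} %")

# Semi-quantitative adiposity of the stroma.
for pct in (0.5, 20, 35):
    print(f"adipose surface {pct:>4}% -> adiposity score {adiposity_score(pct)}")
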