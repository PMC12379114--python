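"""Score the diet index and depression scale for a small hand-made cohort.

Shows the within-cohort quartile logic: each of the eight quartile-scored
components awards 0-3 points by the participant's quartile of consumption,
the alcohol component awards 0/1 by the 20 g/d ethanol threshold, and the
total (0-25) sums the nine.
"""
import pandas as pd

import nordicdiet as nd

cohort = pd.DataFrame({
    "fruits_berries": [10, 80, 30, 50, 70, 20, 60, 40],
    "vegetables": [15, 75, 35, 55, 65, 25, 45, 85],
    "cereals": [100, 800, 300, 500, 700, 200, 600, 400],
    "lowfat_milk": [50, 700, 200, 400, 600, 100, 500, 300],
    "fish": [5, 80, 20, 40, 60, 10, 50, 30],
    "meat_products": [210, 30, 150, 90, 60, 240, 120, 180],
    "total_fat": [44, 30, 38, 34, 32, 46, 36, 40],   # E% of energy
    "pufa": [6, 16, 8, 12, 14, 4, 10, 9],            # g/d
    "sfa": [40, 28, 36, 30, 29, 42, 33, 35],
    "tfa": [2, 2, 2, 2, 1, 3, 2, 1],
    "ethanol": [25, 5, 30, 10, 2, 40, 15, 19],       # g/d
}, dtype=float)

scores = nd.compute_hnds(cohort)
print(scores.to_string())
print()
print("participant 2 is in the most favourable quartile of every component")
print(f"and drinks < 20 g/d, so they reach the ceiling: "
      f"{scores['hnds_total'].iloc[1]} / 25 points")

# HPL example: five symptom answers reach the clinical cut-off
items = [1, 1, 1, 1, 1] + [0] * 13
total = nd.hpl_total(items)
print(f"\nHPL total for five symptom answers: {total} "
      f"-> clinically significant: {nd.classify_depression(total)}")
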