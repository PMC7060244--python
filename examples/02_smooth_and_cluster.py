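"""Smooth LSWT series with ice-aware saturated B-splines and cluster them.

A small three-region population keeps the run fast: fit a knot-per-
observation cubic spline to each lake (coefficients at ice-covered knots
are forced to zero), select the number of groups with the gap statistic,
and K-means the coefficient vectors.
"""

import numpy as np

from lakethermal import (coefficient_matrix, fit_population, gap_statistic,
                         generate_population, kmeans_coefficients,
                         name_clusters, seasonal_profile)

series, truth = generate_population({"NF": 15, "NT": 15, "TH": 15},
                                    n_years=8, seed=3)
fits = fit_population(series)
coefs = coefficient_matrix(fits)
profiles = [seasonal_profile(f) for f in fits]
print(f"coefficient matrix: {coefs.shape[0]} lakes x {coefs.shape[1]} basis functions")

gap = gap_statistic(coefs, k_max=6, B=20, seed=3)
print(f"gap statistic chose k = {gap.chosen_k} "
      f"(gap curve: {np.round(gap.gap, 2)})")

model = kmeans_coefficients(coefs, gap.chosen_k, seed=3)
codes = name_clusters(profiles, model.labels)
labels = [codes[int(c)] for c in model.labels]
agree = np.mean([a == b for a, b in zip(labels, truth)])
print(f"clusters named {sorted(set(labels))}; "
      f"{100 * agree:.0f}% of lakes match their generating region")
# The gap curve flattens once real structure is exhausted; with three well
# separated archetypes the one-standard-error rule stops at k = 3.
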