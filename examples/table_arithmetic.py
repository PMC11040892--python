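"""Reproduce the assay arithmetic of the bundled CHL/IU reference dataset.

Recomputes MN% and relative viability from the raw manual counts and
compares them with the percentages printed in the original report — every
row should reproduce exactly.
"""

from mncount import mn_percentage, relative_viability
from mncount.datasets import chl_iu_manual_counts

df = chl_iu_manual_counts()
control = df[df.chemical == "control"].iloc[0]

print(f"{'group':<16}{'MN% (calc)':>11}{'MN% (pub)':>11}"
      f"{'viab (calc)':>12}{'viab (pub)':>11}")
mismatches = 0
for row in df.itertuples():
    mn_pct = mn_percentage(row.mn_cells, row.total_cells)
    viab = relative_viability(row.total_cells, row.n_images,
                              int(control.total_cells),
                              int(control.n_images))
    label = f"{row.chemical} {row.dose_ug_ml}"
    print(f"{label:<16}{mn_pct:>11.2f}{row.mn_percent_published:>11.2f}"
          f"{viab:>12}{row.viability_percent_published:>11}")
    mismatches += (mn_pct != row.mn_percent_published
                   or viab != row.viability_percent_published)
print()
print(f"{mismatches} mismatching rows: the MN percentage is "
      "100*mn/total rounded to 2 decimals, and viability is the group's "
      "cells-per-image relative to control, rounded to an integer percent.")
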