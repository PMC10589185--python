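"""Simulate and evaluate a full two-method planning study on phantoms.

Six simulated users each instrument two phantom spines with eight screws
(one spine per method), every screw is measured against the pedicle-waist
centre extracted from the voxel masks and graded on the Gertzbein-Robbins
scale, and the two methods are compared: error distributions (Mann-Whitney),
outcome homogeneity (Kruskal-Wallis), and non-inferiority of the success
proportion at a -10 percentage-point margin.
"""

from igtplan import evaluation as ev
from igtplan import phantom as ph

records = ph.simulate_study(n_users=6, n_spines=2, screws_per_spine=8, seed=1)
print(f"{len(records)} graded plans "
      f"({len({r.user for r in records})} users x "
      f"{len({r.patient for r in records})} spines x 8 screws)\n")

summary = ev.summarize_study(records, margin=-0.10)
print(summary.format_table())

mw = summary.mann_whitney
ni = summary.noninferiority
print(f"\nMann-Whitney U on error: U={mw.statistic:.0f}, p={mw.p_value:.3f}")
print(f"Kruskal-Wallis across pedicles: p={summary.kruskal_by_pedicle.p_value:.3f}")
print(f"Kruskal-Wallis across users:    p={summary.kruskal_by_user.p_value:.3f}")
print(f"non-inferiority lower bound (margin -10%): {ni.lower_bound:+.3f} "
      f"-> {'non-inferior' if ni.non_inferior else 'not demonstrated'}")
# a positive lower bound means the test method's success rate is, with 95%
# one-sided confidence, no more than 10 points below the reference method's
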