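"""Simulate a synthetic goat herd and look at the raw recordings.

Builds a small herd with the default trial geometry (2-min trough-weight
sampling over 22 h after the afternoon feed delivery, 5-g scale resolution)
and prints the bookkeeping a real trial would start from.
"""

import numpy as np

import capribite as cb

design = cb.HerdDesign(n_goats=8, n_alpine=3, n_periods=2, n_days_per_period=4)
ds = cb.simulate_herd(design, cb.VarianceSpec(), seed=1)

print(f"goat-day recordings : {len(ds.trough_series)} "
      f"({design.n_goats} goats x {design.n_periods} periods x "
      f"{design.n_days_per_period} days)")
s = ds.trough_series[0]
print(f"samples per series  : {s.t.size} (every {s.interval:.0f} min over "
      f"{design.window_total / 60:.0f} h)")
print(f"first goat-day      : goat {s.goat_id} ({s.breed}), trough starts at "
      f"{s.weight[0]:.0f} g as-fed, ends at {s.weight[-1]:.0f} g")

# conservation: what left the trough equals intake, and refusals close the
# dry-matter balance for every goat-day
feed = ds.feed_table.merge(ds.refusal_table, on=["goat_id", "period", "day"])
truth = ds.truth_days.query("~dropped")
balance = (feed.offered_dm_g.to_numpy()
           - feed.refusal_dm_g.to_numpy()
           - truth.true_intake_dm_g.to_numpy())
print(f"max DM balance error: {np.abs(balance).max():.2e} g (exact by design)")
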