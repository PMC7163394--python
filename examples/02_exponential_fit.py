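"""Fit the exponential intake model y(t) = a(1 - e^{-bt}) to one goat-day.

``a`` estimates the 15-h intake plateau (g DM/kg BW), ``b`` the fractional
rate of intake per minute, and a*b the initial eating rate.  The residual
error (RMSE) is small for goats that eat mostly in one first meal and grows
with the number of separate bouts — so it is itself a behavioural trait.
"""

import capribite as cb

ds = cb.simulate_herd(cb.HerdDesign(n_goats=4, n_alpine=2, n_periods=1,
                                    n_days_per_period=2), seed=3)
bw = {(r.goat_id, r.period): r.bw_kg for r in ds.bw_table.itertuples()}

for series in ds.trough_series[:4]:
    profile = cb.clip_window(
        cb.cumulative_intake(series, bw[(series.goat_id, series.period)]), 900.0)
    fit = cb.fit_exponential(profile)
    n_bouts = len(ds.truth_bouts.query(
        "goat_id == @series.goat_id and period == @series.period and "
        "day == @series.day and kind == 'bout' and start_min < 900"))
    print(f"goat {series.goat_id} {series.day}: a = {fit.a:5.1f} g/kg BW, "
          f"b = {fit.b:.4f}/min, a*b = {fit.ab:.3f} g/kg/min, "
          f"RMSE = {fit.rmse:.2f} g/kg BW  ({n_bouts} true bouts)")

print("\nHigher RMSE flags profiles split over several bouts; the asymptote"
      "\na tracks the goat's 15-h intake per kg of body weight.")
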