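"""Daily oxygen statistics for a hypoxia-prone campaign.

Simulates a calm-wind month in which night-time respiration pulls
dissolved oxygen below the 2 mg/L hypoxia threshold, then prints the
per-day summary the descriptive analysis is built on: daily mean and
minimum DO, percent saturation, and hypoxia flags (daily mean < 2 vs
any step < 2).
"""

import dielmetab as dm

series, _, _ = dm.simulate_campaign(dm.tonle_sap_preset("hypoxic", n_days=30, seed=42))
daily = dm.oxygen_summaries(series)

cols = ["mean_do", "min_do", "pct_sat_mean", "hypoxic_day", "hypoxic_any"]
print(daily[cols].head(10).round(2).to_string())
print(f"\ndays with any hypoxic step : {int(daily.hypoxic_any.sum())} / {len(daily)}")
print(f"days hypoxic in daily mean : {int(daily.hypoxic_day.sum())} / {len(daily)}")
print(f"days below saturation (daily mean) : {int(daily.below_sat_mean.sum())} / {len(daily)}")
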