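"""Accumulate chill hours and chill units over a simulated winter.

Builds one synthetic winter of hourly temperatures, detects the date the
daily mean settles below 7.2 °C (the start of chill accounting), and
sums chill-hour and chill-unit weights up to a mid-January transfer
date.  The printed totals are the winter's chill dose in each model's
units; the CU total is smaller than the CH total here because hours
between 7.2 and 10 °C earn only partial CU credit while hours in the
0-7.2 °C band earn a full CH each.
"""

import pandas as pd

from peonychill import (
    ChillHourModel,
    ChillUnitModel,
    WinterConfig,
    detect_start_date,
    format_chill,
    hourly_accumulate,
    simulate_winter,
)

winter = simulate_winter(WinterConfig(seed=1, season_label="example winter"))
print(f"simulated {len(winter)} hourly readings, {winter.start:%b %d} .. {winter.end:%b %d}")

start = detect_start_date(winter, threshold=7.2, persistence_days=3)
print(f"chill accounting starts {start:%Y-%m-%d} (3 consecutive days below 7.2 °C)")

transfer = pd.Timestamp("2013-01-21 10:00")
for model in (ChillHourModel(), ChillUnitModel()):
    total = hourly_accumulate(winter, (start, transfer), model)
    print(f"  {model.unit} accumulated to {transfer:%b %d %H:%M}: {format_chill(total):.2f}")

# refrigerated storage needs no hourly record: constant 2 °C for 4 weeks
from peonychill import constant_accumulate

print(f"  4 weeks at constant 2 °C: {format_chill(constant_accumulate(2.0, 672, ChillUnitModel())):.2f} CU")
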