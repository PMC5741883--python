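#!/usr/bin/env python
"""Optional verification against the study's downloaded hourly weather record.

The natural-chill worked example — 46.00 chilling hours accumulated from
00:00 Dec 8, 2012 to the 10:00 Dec 10, 2012 transfer — needs the
original hourly temperature record (the study's supplementary winter
weather table, exported to CSV with columns ``timestamp, temp_c``),
which is not shipped with the package.  Point ``--temps`` at that export
to verify:

    python scripts/verify_natural_chill.py --temps additional_file_3.csv

``--selftest`` instead exercises the same code path on a synthetic
constant-temperature series whose expected total is known exactly.
"""

import argparse
import sys

import pandas as pd

from peonychill import ChillHourModel, HourlyTemperatureSeries, format_chill, hourly_accumulate

WINDOW_START = pd.Timestamp("2012-12-08 00:00")
WINDOW_END = pd.Timestamp("2012-12-10 10:00")  # Tre. 1-2 transfer instant
EXPECTED_CH = 46.00


def verify(series: HourlyTemperatureSeries, start, end, expected: float) -> int:
    total = hourly_accumulate(series, (start, end), ChillHourModel(), interpolate_gaps=True)
    got = format_chill(total)
    status = "OK" if got == expected else "MISMATCH"
    print(f"[{status}] CH over [{start}, {end}): computed {got:.2f}, expected {expected:.2f}")
    return 0 if got == expected else 1


def selftest() -> int:
    # 58 in-band hours at 5 °C over the same window shape: expected = 58.00
    idx = pd.date_range(WINDOW_START, WINDOW_END, freq="h", inclusive="left")
    series = HourlyTemperatureSeries(pd.Series(5.0, index=idx))
    return verify(series, WINDOW_START, WINDOW_END, 58.00)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--temps", help="CSV of the winter 2012-2013 hourly record")
    parser.add_argument("--selftest", action="store_true")
    args = parser.parse_args()
    if args.selftest:
        sys.exit(selftest())
    if not args.temps:
        parser.error("--temps required unless --selftest")
    from peonychill.io import load_temperature_table

    series = load_temperature_table(args.temps)
    sys.exit(verify(series, WINDOW_START, WINDOW_END, EXPECTED_CH))


if __name__ == "__main__":
    main()
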