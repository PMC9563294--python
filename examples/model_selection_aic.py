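"""Rank candidate distributions for the positive wind-speed values by AIC.

Fits eight families to each province's positive observations by maximum
likelihood and prints them sorted by AIC (smaller is better).  The
three-parameter lognormal and plain lognormal dominate the symmetric
families, reflecting the right skew of wind-speed data.
"""

from tplnz import aic_table, wind_speed

ds = wind_speed()
for label, sample in zip(ds.group_labels, ds.samples):
    print(f"{label} (n1 = {sample.n1} positive values):")
    for row in aic_table(sample):
        flag = "" if row.ok else "  [fit failed]"
        print(f"  {row.family:12s} k = {row.k_params}  "
              f"AIC = {row.aic:9.4f}{flag}")
    print()
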