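"""Simulate one treatment-year of the vegetable rotation.

Builds the conventional-irrigation, conventional-fertiliser scenario
(W1N1) for the wet study year from the synthetic generators, runs the
daily water-nitrogen-crop loop, and prints the per-season ledgers.
The Wbalance/Nbalance columns are the storage residuals of the 0.9 m
profile: positive means the season left water or nitrogen behind.
"""

from vegrot import default_config, run_rotation

result = run_rotation(default_config("W1N1", 2000, seed=1))

print(f"{len(result.daily)} days simulated "
      f"(max |water closure| {result.daily['water_residual'].abs().max():.1e} mm, "
      f"max |N closure| {result.daily['n_residual'].abs().max():.1e} kg N/ha)\n")

hdr = (f"{'season':<12}{'RF':>7}{'I':>8}{'ET':>8}{'D':>7}{'Y':>9}"
       f"{'WUE':>6}{'Nup':>7}{'Ngas':>7}{'Nlea':>7}{'Nbal':>8}")
print(hdr)
for s in result.seasons + result.annual:
    print(f"{s.crop:<12}{s.rainfall:>7.1f}{s.irrigation:>8.1f}{s.et:>8.1f}"
          f"{s.drainage:>7.1f}{s.yield_fresh:>9.0f}{s.wue:>6.1f}"
          f"{s.uptake_n:>7.1f}{s.gaseous_n:>7.1f}{s.leached_n:>7.1f}"
          f"{s.nbalance:>8.1f}")
print("\nUnits: water mm, yield kg/ha, WUE kg/m3, N terms kg N/ha.")
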