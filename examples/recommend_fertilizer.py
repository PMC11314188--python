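"""Compute a budget-based optimal N fertiliser dose.

The recommendation balances the expected crop uptake, a target
post-harvest residual and an empirical loss term (1.9 % of the
farmer-practice rate per week of season) against the mineral N already
in the root zone and the mineralisation credit. The reduced variant
applies the 80 % dose used for the most conservative treatment.
"""

from vegrot import RecommendationInputs, recommend_n, reduced_rate
from vegrot.expertn import n_loss_estimate

inputs = RecommendationInputs(
    n_upt=200.0,          # expected seasonal crop uptake, kg N/ha
    n_res=50.0,           # target residual mineral N after harvest
    n_ini=100.0,          # measured mineral N at season start
    n_hum=30.0,           # expected humus mineralisation over the season
    n_root=0.0,           # residues removed from the field
    n_input_farmer=450.0, # conventional rate, drives the loss estimate
    season_weeks=10.0,
)

loss = n_loss_estimate(inputs.n_input_farmer, inputs.season_weeks)
n_opt = recommend_n(inputs)
print(f"estimated seasonal loss at farmer practice: {loss:.1f} kg N/ha")
print(f"optimal dose N_opt:                          {n_opt:.1f} kg N/ha")
print(f"reduced (80 %) dose:                         {reduced_rate(n_opt):.1f} kg N/ha")
print("\nA dose of 0 means the soil already covers the crop's needs.")
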