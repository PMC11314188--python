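"""Score simulated water contents against noisy pseudo-observations.

Runs a scenario, samples TDR-style observations of the topsoil water
content (every 2 days, Gaussian noise) from the simulated truth, and
evaluates the simulation against them with the RMSE / Nash-Sutcliffe E
/ agreement-index d triple. Because the observations are noised truth,
the scores show the ceiling imposed by observation noise alone; the
acceptability rule is E > 0.36 and d > 0.7.
"""

from vegrot import (acceptance_check, default_config, evaluate_series,
                    generate_observations, run_rotation)

result = run_rotation(default_config("W1N1", 2000, seed=1))
obs = generate_observations(result.daily, noise_sd_theta=0.02,
                            noise_sd_no3=2.0, seed=7)

for layer in ("theta_0_15", "theta_60_90"):
    sim = result.daily[layer].to_numpy()[obs.water_days]
    stats = evaluate_series(sim, obs.water[layer])
    verdict = acceptance_check(stats)
    print(f"{layer}: RMSE {stats.rmse:.3f} cm3/cm3, E {stats.nse:.2f}, "
          f"d {stats.agreement:.2f}, n {stats.n} -> "
          f"{'acceptable' if verdict['acceptable'] else 'not acceptable'}")
print("\nRMSE is in the variable's own units; E=1 and d=1 are perfect.")
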