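"""Global two-site-exchange fit of an in-vivo multi-field FFC dataset.

Simulates pre-polarized magnetization decays of a tumor-bearing limb at
the seven analysis fields (0.01-1 MHz proton Larmor frequency) and fits
them simultaneously, sharing the extracellular volume fraction v_ex and
the extracellular water lifetime tau_ex across fields while holding the
extracellular rate fixed to the Matrigel phantom table.  No contrast
agent is needed: at these low fields the intrinsic intra/extracellular
rate difference itself provides the shutter-speed contrast.
"""

import shutterspeed as ss

dispersion = ss.default_dispersion_truth()
v_ex_true, k_io_true = 0.30, 0.8
tau_ex_true = 1.0 / ss.influx_from_efflux(k_io_true, v_ex_true)

dataset = ss.gen_nmrd_dataset(dispersion, v_ex=v_ex_true,
                              tau_ex=tau_ex_true, noise=0.02, seed=7)
fit = ss.fit_nmrd_global(dataset)

print(f"true  v_ex = {v_ex_true:.3f}   k_io = {k_io_true:.3f} s^-1")
print(f"fitted v_ex = {fit.estimates['v_ex']:.3f} "
      f"+/- {fit.std_errors['v_ex']:.3f}")
print(f"fitted k_io = {fit.estimates['k_io']:.3f} "
      f"+/- {fit.std_errors['k_io']:.3f} s^-1  (derived from tau_ex, v_ex)")
print()
print("per-field intracellular rate and effective dispersion profile:")
for field, r1_obs in sorted(fit.diagnostics["r1_obs_profile"].items()):
    r1_in = fit.estimates[f"r1_in@{field:g}MHz"]
    print(f"  {field:>5g} MHz : r1_in = {r1_in:6.3f} s^-1, "
          f"observed R1 = {r1_obs:6.3f} s^-1")
print()
print("The observed-R1 column is what a 1/T1 dispersion profile plots;")
print("its elevation over the extracellular rate carries the exchange")
print("information from which k_io and v_ex are extracted.")
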