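"""Longitudinal treatment-response study at desk scale.

Simulates a treated-vs-control mouse cohort (n=4/arm here for speed;
the full design uses 7) followed over a treatment course: the treated
arm's efflux rate drops 40% after the first treatment and returns to
baseline, while its extracellular fraction first dips then grows as
dying cells' membranes become freely water-permeable.  Every animal's
multi-field dataset is fitted globally and the cohort is summarized with
Welch tests per timepoint.
"""

import shutterspeed as ss
from shutterspeed.nmrd import GlobalFitSpec

truth = ss.CohortTruth(n_per_arm=4, seed=3)
records, manifest = ss.gen_cohort(truth, n_tau=16)

spec = GlobalFitSpec(v_ex_starts=(0.33,), tau_ex_starts=(0.5,),
                     uncertainties=False)
fits = [(rec["arm"], rec["timepoint"],
         ss.fit_nmrd_global(rec["dataset"], spec)) for rec in records]

summary = ss.longitudinal_summary(fits)
cols = ["timepoint", "arm", "mean_k_io", "sd_k_io", "mean_v_ex",
        "p_k_io_vs_control", "p_v_ex_vs_control"]
print(summary[cols].to_string(index=False, float_format="%.3f"))
print()
print("Days are relative to the first treatment (acquisitions 3 days")
print("after each of three treatments).  The treated arm's k_io dip at")
print("day 3 with recovery afterwards, and its rising v_ex, are the")
print("programmed early-response signatures the fit should recover.")
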