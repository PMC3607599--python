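"""Classify spore fates and compare two populations with the F-then-t protocol.

Builds two scripted record populations at the scale of a real experiment
(218 untreated vs 325 heat-stressed spores), classifies fates, and compares
start-of-germination distributions drawn at the reported moments.  The
F-test decides between the pooled and Welch t-test.
"""

import numpy as np

from sporetrace import SporeRecord, classify_fates, compare_conditions


def scripted(n, frac_germ, frac_out):
    n_g, n_o = round(frac_germ * n), round(frac_out * n)
    return [
        SporeRecord(
            spore_id=i,
            fate="outgrow" if i < n_o else ("germinate_only" if i < n_g else "dormant"),
        )
        for i in range(n)
    ]


control = classify_fates(scripted(218, 0.940, 0.847))
stress = classify_fates(scripted(325, 0.529, 0.363))
print(f"control:  {control.fraction_germinated_pct:.1f}% germinated, "
      f"{control.fraction_outgrown_pct:.1f}% outgrown (n={control.n_assessed})")
print(f"stressed: {stress.fraction_germinated_pct:.1f}% germinated, "
      f"{stress.fraction_outgrown_pct:.1f}% outgrown (n={stress.n_assessed})")
print(f"drop: {control.fraction_germinated_pct - stress.fraction_germinated_pct:.1f} pp "
      f"germinated, {control.fraction_outgrown_pct - stress.fraction_outgrown_pct:.1f} pp outgrown")

rng = np.random.default_rng(3)
starts_control = rng.normal(63.0, 56.0, 171)
starts_stress = rng.normal(82.0, 68.0, 152)
cmp = compare_conditions(starts_control, starts_stress, "start_of_germination_min")
print(f"start of germination: {cmp.mean_a:.0f}+-{cmp.sd_a:.0f} vs "
      f"{cmp.mean_b:.0f}+-{cmp.sd_b:.0f} min; "
      f"F p={cmp.f_p_value:.3f} -> {cmp.t_variant} t-test, p={cmp.t_p_value:.4f}")
# A significant t-test at alpha=0.05 means the stressed population starts
# germinating later on average.
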