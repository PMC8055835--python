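"""Generate a calibrated two-arm pseudo-trial and summarize it.

The default calibration reproduces the published summary profile of a
first-line ES-SCLC immunotherapy trial: median OS 12.3 vs 10.3 months,
1-year OS 51.7% vs 38.2%, median PFS 5.2 vs 4.3 months, OS HR ≈ 0.70.
"""

from psmcure import cox_hazard_ratio, default_calibration, generate_ipd, kaplan_meier

spec_i, spec_c, life_table = default_calibration((2000, 2000))
dataset = generate_ipd([spec_i, spec_c], life_table, seed=1)

print(f"simulated {len(dataset)} patients in arms {dataset.arms}")
for arm in dataset.arms:
    km_os = kaplan_meier(dataset, "os", arm)
    km_pfs = kaplan_meier(dataset, "pfs", arm)
    print(
        f"  {arm:>4}: median OS {km_os.median:5.2f} mo | "
        f"1-yr OS {100 * float(km_os.survival_at(12.0)):.1f}% | "
        f"median PFS {km_pfs.median:.2f} mo"
    )
hr_os = cox_hazard_ratio(dataset, "os", "A+C", "C")
hr_pfs = cox_hazard_ratio(dataset, "pfs", "A+C", "C")
print(f"Cox hazard ratios: OS {hr_os:.3f}, PFS {hr_pfs:.3f}")
print("(values should sit near the published 0.70 / 0.77 within Monte-Carlo noise)")
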