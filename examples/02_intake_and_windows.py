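"""Protein quantification, level classification and lag-lead windows.

Shows the amino-acid conversion, the level boundaries, the level-II
imputation after live ICU discharge, and which follow-up intervals a given
day on diet can influence under the dynamic and static windows.
"""

import numpy as np

import icupam as ip

day = ip.DietDay(day_index=2, en_protein=0.5, pn_amino_acids=0.6)
total = ip.total_protein(day)
print(f"EN 0.5 + PN 0.6 g/kg amino acids -> {total:.3f} g/kg protein-equivalent")
print(f"  (PN amino acids count with factor {ip.PN_TO_PROTEIN})")
for g in (0.49, 0.8, 0.99, 1.2, 1.41):
    print(f"  {g:4.2f} g/kg -> level {ip.classify_day(g)}")

patient = ip.PatientRecord(
    patient_id=1, icu_id=3, age=64, sex="male", bmi=28, apache2=24,
    admission_category="medical", diagnosis="dx4", year=2013,
    days_mv=3, days_pn=1, days_oral=0, days_propofol=2,
    intake_days=[ip.DietDay(j, 0.95, 0.0) for j in range(1, 7)],
    outcome="live_discharge", outcome_time=21.0, icu_discharge_day=6,
)
traj = ip.build_trajectory(patient, mode="hospital")
print("\nhospital-mode trajectory (ICU discharge on day #6):")
print("  levels:", [d.level for d in traj])
print("  imputed days:", [d.day_index for d in traj if d.imputed])
print("  icu-mode trajectory length:", len(ip.build_trajectory(patient, mode="icu")))

grid = ip.IntervalGrid()
for mode in ("dynamic", "static"):
    window = ip.build_window(traj, grid, mode)
    active = np.flatnonzero(window.W[:, 4])  # day on diet #5
    lo, hi = grid.t_start[active[0]], grid.t_start[active[-1]]
    print(f"\n{mode} window: day #5 affects intervals starting in [{lo:.0f}, {hi:.0f}]")
print("(the 4-day lag means no diet day can touch the interval (4,5])")
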