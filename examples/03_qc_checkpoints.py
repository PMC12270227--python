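"""Quality-control checkpoints on synthetic control wells.

ChP2: a linear classifier on 23 brightfield features estimates the percent
of activated cells per control well; the plate gate applies the printed
rules.  ChP5: abnormal control CP scores drive renormalize / rescreen /
repeat decisions.
"""

import pandas as pd

import cpscreen as cp

# --- ChP2: train on two resting + two activated wells, gate the plate
train = cp.simulate_brightfield_cells(
    {"B02": 0.0, "B03": 0.0, "C02": 1.0, "C03": 1.0}, cells_per_well=300, seed=1,
    separation=2.5,
)
model = cp.train_activation_classifier(train)
print(f"classifier training accuracy: {100 * model.training_accuracy:.1f}%")

fractions = {f"D{i:02d}": 0.05 for i in range(2, 18)}        # 16 noPMA controls
fractions.update({f"E{i:02d}": 0.65 for i in range(2, 18)})  # 16 PMA controls
wells = cp.simulate_brightfield_cells(fractions, cells_per_well=250, seed=2, separation=2.5)
records = []
for well, grp in wells.groupby("well"):
    records.append({
        "well": well,
        "condition": "resting" if well.startswith("D") else "activated",
        "percent_activated": cp.percent_activated(model, grp),
    })
percents = pd.DataFrame(records)
decision = cp.chp2_gate(percents, plate_id="P01")
print(f"ChP2 verdict: {decision.verdict}  evidence: {decision.evidence}")
print("  (pass: <=2 noPMA controls over 15% activated, <=2 PMA controls under 30%)")

# --- ChP5: 5 of 40 reference controls score active -> renormalize
controls = pd.DataFrame({
    "role": ["reference_control"] * 40,
    "cp_score": [2.0] * 5 + [0.1] * 35,
})
d5 = cp.chp5_gate(controls, threshold=1.0, plate_id="P01")
print(f"ChP5 verdict: {d5.verdict}  "
      f"(abnormal at outset: {d5.evidence['n_abnormal_outset']}/40)")
print("  (more than 3 abnormal controls: drop them and renormalize the plate)")
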