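"""One noise-free virtual subject under closed-loop control.

Builds an insulin-resistant ICU patient at a hyperglycemic steady state
(~10-11 mM), then lets the adaptive MPC dose insulin/dextrose every 5 minutes
from perfect glucose observations. Prints the hourly glucose/insulin profile:
glucose should settle into the 6.0-8.0 mM target band within a few hours and
the slow parameter b_est should approach the patient's true steady insulin
requirement.
"""

from dataclasses import replace

from iculoop import controller as C
from iculoop.patient import (
    ConstantResistance,
    ExogenousInput,
    basal_for_glucose,
    make_cohort,
    steady_state,
    step,
)

CHO = 7.5  # g/h enteral carbohydrate, held constant

patient = replace(make_cohort(1, seed=2)[0],
                  resistance_profile=ConstantResistance(1.0))
b_true = basal_for_glucose(patient, 7.0, CHO=CHO)
state = steady_state(patient, patient.basal_insulin, CHO=CHO)
cs = C.initialize(patient.weight, state.glucose(patient))

print(f"subject: {patient.weight:.0f} kg, entry glucose "
      f"{state.glucose(patient):.1f} mM, true requirement {b_true:.2f} U/h")
print(f"{'hour':>4} {'G (mM)':>7} {'insulin (U/h)':>14} {'b_est (U/h)':>12}")

u = dex = 0.0
for t in range(24 * 60):
    G = state.glucose(patient)
    if t % 5 == 0:
        _, cmd = C.control_cycle(cs, t, G)
        u, dex = cmd.insulin, cmd.dextrose
    if t % 120 == 0:
        print(f"{t // 60:>4} {G:>7.2f} {u:>14.2f} {cs.b_est:>12.2f}")
    state = step(state, patient, ExogenousInput(u, dex, CHO), 1.0)

print(f"\nafter 24 h: glucose {state.glucose(patient):.2f} mM "
      f"(target band 6.0-8.0), b_est {cs.b_est:.2f} vs true {b_true:.2f} U/h")
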