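"""From raw dual-wavelength absorbances to QC-validated net OD values.

Builds one small plate by hand — a subject's antigen and background
triplicates plus the two plate controls — validates the controls against
their expected ODs (±10%), and computes the control-corrected net value.
"""

from seroindex import (
    PlateRun,
    QCConfig,
    ReplicateGroup,
    WellRole,
    compute_od,
    process_plate,
)

# per-well OD is A450 minus the A620 reference reading
od = compute_od(a450=1.02, a620=0.05)
print(f"single well: A450 1.02, A620 0.05 -> OD {od:.2f}")

plate = PlateRun(
    plate_id="demo",
    groups=[
        ReplicateGroup("S1", "cit-DL", WellRole.ANTIGEN, [0.90, 1.00, 1.10]),
        ReplicateGroup("S1", "", WellRole.BACKGROUND, [0.20, 0.20, 0.20]),
    ],
    secondary_control=ReplicateGroup("", "", WellRole.SECONDARY_CONTROL, [0.05, 0.05, 0.05]),
    positive_control=ReplicateGroup("", "", WellRole.POSITIVE_CONTROL, [1.02, 0.98, 1.00]),
)

config = QCConfig(expected_positive_control_od=1.0, expected_secondary_od=0.05)
qc, nets = process_plate(plate, config)
print(f"plate QC valid: {qc.valid} (controls within ±{config.qc_tolerance:.0%})")
for n in nets:
    print(
        f"sample {n.sample_id}, antigen {n.antigen_id}: net OD {n.value:.2f} "
        f"(antigen CV {n.replicate_cv_antigen:.1%}, flags: {sorted(n.qc_flags) or 'none'})"
    )
# The net value is mean(antigen) - mean(background); the secondary-antibody
# control cancels out of the two corrected means but is logged for audit.
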