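"""The citrullinated-minus-native delta index and the combined panel.

Generates the built-in demo study, computes per-subject CN-index values,
derives the three marker cutoffs from the synthetic healthy controls and
other-disease cohort, and prints a dual-cutoff sensitivity table
(healthy-control cutoff left of the slash, other-disease cutoff right).
"""

from seroindex import PipelineConfig, cn_index, demo_spec, generate_study
from seroindex.panel import build_sensitivity_table
from seroindex.pipeline import compute_reference_cutoffs

study = generate_study(demo_spec(seed=3, scale=0.5))
records = study.subject_records

idx = cn_index(records[0].cit_net, records[0].native_net, records[0].subject_id)
print(
    f"subject {idx.subject_id}: delta = cit - native = {idx.delta:+.3f} OD "
    f"({idx.sign_class}{', strong negative' if idx.strong_negative else ''})"
)
# a negative index means the native signal dominates; below -0.1 OD it is
# annotated as strongly negative, a pattern typical of lupus sera

cutoffs = compute_reference_cutoffs(records, PipelineConfig(target_specificity=0.98))
table = build_sensitivity_table(records, cutoffs)
view = table[table.stratum == "all"].pivot(index="cohort", columns="marker", values="cell")
print("\npercent positive (healthy-control cutoff / other-disease cutoff):")
print(view[["cit", "native", "delta", "total"]].to_string())
# "total" is the combined panel: positive when any of the three markers
# exceeds its own cutoff, so each total cell is >= the row's largest single
# marker
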