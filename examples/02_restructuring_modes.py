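"""How a specification mask restructures the complaint predictors.

Shows the same three patients under the four design modes.  With
"abdominal cramping" selected, the flattened design moves that patient out
of the "abdominal pain" category (mutually exclusive single level), while
the hierarchical design keeps the category indication and adds the
specific complaint on top.
"""
from levelopt import (
    Cohort, ComplaintHierarchy, PatientRecord, SpecificationMask, build_design,
)

hierarchy = ComplaintHierarchy.from_pairs([
    ("abdominal cramping", "abdominal pain"),
    ("abdominal mass", "abdominal pain"),
    ("tension headache", "headache"),
])

def visit(complaint, outcome):
    return PatientRecord(
        age_band="40-49", gender="female", arrival_mode="walk_in",
        temperature_cat="96.1-99.2", pulse_cat="59-105", resp_rate_cat="14-19",
        bp_cat="106-176", o2sat_cat=">94", complaint=complaint, outcome=outcome,
    )

cohort = Cohort.from_records(
    [visit("abdominal cramping", 1), visit("abdominal mass", 0),
     visit("tension headache", 0)],
    hierarchy,
)
mask = SpecificationMask.from_selected(hierarchy, ["abdominal cramping"])

for mode in ("complaints_only", "categories_only", "flattened", "hierarchical"):
    design = build_design(cohort, mask, mode)
    level = design.to_frame()[[c for c in design.column_names
                               if c.startswith(("complaint=", "category="))]]
    print(f"\n--- {mode} ---")
    print(level.to_string(index=True))
# Rows are the cramping / mass / headache patients in order: flattened rows
# sum to one across the complaint-level columns; hierarchical keeps
# abdominal pain = 1 even for the cramping patient.
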