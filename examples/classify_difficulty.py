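"""Classify docking difficulty from conformational-change metrics.

A case is Rigid when I-RMSD < 1.5 A and f_non-nat < 0.40, Difficult when
I-RMSD > 2.2 A, and Medium otherwise.  The six metric pairs below are
published representatives of the three categories; the composition table
shows the share arithmetic used in benchmark reports.
"""

from dockbench import classify_case, summarize_benchmark
from dockbench.difficulty import render_summary_table

examples = [
    ("6JB8", 0.938, 0.344, "sdAb"),
    ("6Q0O", 0.574, 0.141, "mAb"),
    ("6HHD_1", 2.153, 0.545, "sdAb"),
    ("6OEJ", 0.965, 1.000, "mAb"),
    ("6HER", 2.354, 0.583, "sdAb"),
    ("6OFI", 2.956, 0.661, "mAb"),
]

entries = []
for case_id, irmsd, fnn, ab_type in examples:
    label = classify_case(irmsd, fnn)
    entries.append((case_id, label, ab_type))
    print(f"{case_id:8s}  I-RMSD={irmsd:5.3f} A  f_non-nat={fnn:5.3f}  ->  {label}")

print()
print(render_summary_table(summarize_benchmark(entries)))
print()
print("Each share is the percentage of cases in that difficulty category;")
print("the sdAb/mAb columns split them by antibody type.")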