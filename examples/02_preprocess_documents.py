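"""Normalization and history-document construction.

Shows the date/measurement token substitution, the chronological
concatenation that turns a patient's reports into one history document per
target exam, and the 70/15/15 split arithmetic that reproduces the
published per-organ split sizes.
"""

from metmap import (
    OrganSite,
    build_history_document,
    build_timelines,
    calibrated_params,
    make_corpus,
    normalize_text,
    split_sizes,
)

raw = "New nodule measuring 1.2 x 0.8 cm, unchanged since 3/14/2019."
print("raw:       ", raw)
print("normalized:", normalize_text(raw))
# the measurement's value is noise, its presence is signal

corpus, _ = make_corpus(50, seed=4, params=calibrated_params(seed=0))
timeline = max(build_timelines(corpus), key=len)
print(f"\npatient {timeline.patient_id}: {len(timeline)} exams")
for t in range(min(3, len(timeline))):
    doc = build_history_document(timeline, t, OrganSite.LUNGS)
    print(f"\nhistory document for exam {t} (label={doc.label}):")
    print("  " + doc.text.replace("\n", "\n  "))
# each document is a prefix of the next: exam t's document concatenates
# the lung findings of exams 0..t oldest-to-newest

print("\n70/15/15 split sizes (train, test, validation):")
for n in (7733, 2777, 4107):
    print(f"  N={n}: {split_sizes(n)}")
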