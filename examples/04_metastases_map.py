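"""Weak-label a corpus and assemble patient-level metastases maps.

Trains a Simple CNN per organ on a small synthetic corpus, labels every
report of a held-out corpus, and prints one patient's predicted
per-organ label series with the derived first-positive dates — the
patient × organ × time matrix a digital-twin pipeline consumes.
"""

from metmap import (
    OrganSite,
    build_documents,
    build_metastases_map,
    build_timelines,
    calibrated_params,
    make_corpus,
    split_dataset,
)
from metmap.nn.classifiers import SimpleCNNClassifier
from metmap.nn.models import TrainConfig

params = calibrated_params(seed=0)
train_corpus, _ = make_corpus(500, seed=5, params=params)
fresh_corpus, _ = make_corpus(60, seed=6, params=params)

classifiers = {}
for organ in (OrganSite.LUNGS, OrganSite.LIVER):
    docs = build_documents(build_timelines(train_corpus), organ, history=True)
    split = split_dataset([d.target_report_id for d in docs], seed=5)
    tr = [d for d in docs if split.assignment[d.target_report_id] == "train"]
    va = [d for d in docs if split.assignment[d.target_report_id] == "validation"]
    clf = SimpleCNNClassifier(seed=5)
    clf.fit(
        [d.text for d in tr], [d.label for d in tr],
        [d.text for d in va], [d.label for d in va],
        TrainConfig(epochs=10, patience=3, seed=5),
    )
    classifiers[organ] = clf

mmap = build_metastases_map(fresh_corpus, classifiers)
print(f"map rows: {len(mmap.table)} "
      f"({len(fresh_corpus)} reports x {len(classifiers)} organs)")

firsts = mmap.first_positive_dates()
print(f"patients with a predicted first-positive date: "
      f"{firsts['patient_id'].nunique()}")

pid = firsts["patient_id"].iloc[0]
print(f"\npredicted series for patient {pid}:")
sub = mmap.table[mmap.table["patient_id"] == pid]
for organ, og in sub.groupby("organ"):
    series = " ".join(
        f"{d[5:]}:{l}" for d, l in zip(og["exam_date"], og["label"])
    )
    print(f"  {organ:15s} {series}")
print("\nfirst-positive dates:")
print(firsts[firsts["patient_id"] == pid].to_string(index=False))
# labels are weak (model-generated); the first-positive date estimates the
# exam at which metastatic disease was first reported for that organ
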