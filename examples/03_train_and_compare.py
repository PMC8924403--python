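"""Train the baseline and the multi-report models on one synthetic corpus.

Fits the single-report TF-IDF soft-voting ensemble and the two CNNs on a
shared 70/15/15 split of a 600-patient lung corpus and prints validation
metrics side by side.  With q_stable = 0.7, most persisting metastases are
reported only as "stable/no change": the single-report baseline loses
them (low recall), while the multi-report models recover them from the
history.
"""

from metmap import OrganSite, calibrated_params, make_corpus, run_model_comparison
from metmap.nn.models import TrainConfig

params = calibrated_params(q_stable=0.7, seed=0)
corpus, _ = make_corpus(600, seed=2, params=params)
print(f"corpus: {len(corpus)} reports from 600 patients")

result = run_model_comparison(
    corpus,
    OrganSite.LUNGS,
    seed=2,
    models=("baseline", "cnn", "acnn"),
    train_config=TrainConfig(epochs=12, patience=3, seed=2),
)
print(f"\n{'model':10s} {'accuracy':>9s} {'precision':>10s} {'recall':>7s} {'f1':>7s}")
for model, per_split in result.metrics.items():
    rep = per_split["validation"]
    print(
        f"{model:10s} {rep.accuracy:9.4f} {rep.precision:10.4f} "
        f"{rep.recall:7.4f} {rep.f1:7.4f}"
    )
# expected shape: baseline recall well below the CNNs' -- the follow-up
# positives whose own report says only 'stable' are invisible to it
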