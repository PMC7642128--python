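#!/usr/bin/env python
"""Left-vs-right classification: CNN vs LSTM under stratified 5-fold CV.

Runs both architectures on identical folds of the denoised competition-
protocol session, writes results/cv_comp118.json, and prints per-fold and
mean accuracies plus the paired fold differences.  The expected pattern on
this generator: near-ceiling CNN accuracy (the class signal is spectral-
spatial) and chance-level LSTM (the temporal envelope carries almost no
class information).
"""

import json
from pathlib import Path

from mieeg import classify as clf
from mieeg import eeg_io

SESSIONS = Path("results/sessions")
OUT = Path("results")


def main() -> None:
    pre = eeg_io.read_epochs(SESSIONS / "comp118_denoised")
    configs = [clf.ClassifierConfig(arch="cnn", seed=201),
               clf.ClassifierConfig(arch="lstm", seed=201)]
    comp = clf.compare_archs(pre, configs, k=5)

    payload = {name: rep.to_dict() for name, rep in comp["reports"].items()}
    payload["paired_fold_differences"] = comp["paired_fold_differences"]
    payload["ranking"] = comp["ranking"]
    (OUT / "cv_comp118.json").write_text(json.dumps(payload, indent=1))

    for name, rep in comp["reports"].items():
        folds = ", ".join(f"{a:.3f}" for a in rep.fold_accuracies)
        print(f"{name}: folds [{folds}] mean {rep.mean_accuracy:.3f} "
              f"(sd {rep.std_accuracy:.3f})")
    diffs = comp["paired_fold_differences"]["cnn-lstm"]
    print(f"cnn - lstm per fold: {[round(d, 3) for d in diffs]}")
    print(f"ranking: {comp['ranking']} -> results/cv_comp118.json")


if __name__ == "__main__":
    main()
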