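#!/usr/bin/env python
"""Frequency-domain analysis: periodogram PSDs and ERD/ERS tables.

Writes results/psd_comp118.csv (trial-averaged C3/C4 PSD per class) and
results/erd_comp118.csv (ERD/ERS percentages per channel and band for both
classes), and prints the lateralization pattern — contralateral mu/beta
desynchronization, ipsilateral synchronization.
"""

from pathlib import Path

import pandas as pd

from mieeg import eeg_io
from mieeg.core import LABELS
from mieeg.erd_ers import erd_ers_map
from mieeg.spectral import epoch_psd

SESSIONS = Path("results/sessions")
OUT = Path("results")


def main() -> None:
    es = eeg_io.read_epochs(SESSIONS / "comp118")

    psd_rows = []
    for label in LABELS:
        sub = es.select_label(label)
        for ch in ("C3", "C4"):
            res = epoch_psd(sub.data[:, sub.channel_index(ch), :], sub.fs)
            psd_rows += [
                {"label": label, "channel": ch, "freq_hz": f, "psd": p}
                for f, p in zip(res.freqs, res.psd)
            ]
    pd.DataFrame(psd_rows).to_csv(OUT / "psd_comp118.csv", index=False)

    erd_rows = []
    for label in LABELS:
        res = erd_ers_map(es, label)
        t = res.table.copy()
        t.insert(0, "label", label)
        erd_rows.append(t)
    erd = pd.concat(erd_rows, ignore_index=True)
    erd.to_csv(OUT / "erd_comp118.csv", index=False)

    print(erd.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    for label, contra in (("left", "C4"), ("right", "C3")):
        row = erd[(erd.label == label) & (erd.channel == contra) & (erd.band == "mu")]
        print(f"{label}-hand imagery: mu ERD at contralateral {contra} = "
              f"{row.erd_ers_percent.iloc[0]:.1f}%")


if __name__ == "__main__":
    main()
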