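#!/usr/bin/env python
"""Generate the synthetic motor-imagery sessions the analysis runs on.

Emits two sessions under results/sessions/:
  * ``comp118`` — the competition-style protocol (118 electrodes, 100 Hz,
    140 trials per class) with a moderate injected effect;
  * ``lab32`` — the 32-lead, 250 Hz laboratory protocol.

Prints the protocol summary for each.
"""

from pathlib import Path

from mieeg import eeg_io, synthgen

OUT = Path("results/sessions")


def main() -> None:
    for preset, kwargs in [
        ("comp118", dict(erd_depth=0.5, ers_gain=0.1, snr_db=5.0, seed=101)),
        ("lab32", dict(erd_depth=0.5, ers_gain=0.1, snr_db=5.0, seed=102)),
    ]:
        cfg = synthgen.GeneratorConfig(preset=preset, **kwargs)
        es = synthgen.generate_session(cfg)
        eeg_io.write_epochs(es, OUT / preset)
        print(
            f"{preset}: {es.n_trials} trials {es.class_counts()}, "
            f"{es.n_channels} ch @ {es.fs:g} Hz, "
            f"{es.n_samples} samples/trial (cue at {es.cue_index}) "
            f"-> {OUT / preset}"
        )


if __name__ == "__main__":
    main()
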