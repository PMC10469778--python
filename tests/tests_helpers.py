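"""Shared constructors for hand-built test sessions."""

import numpy as np

from speechbeta.session_io import Annotation, SessionRecording


def session_from_gaps(gap_ms, labels=None, fs=200.0, invalid=(), lead_s=2.0):
    """Session with 0.4 s utterances (0.1 C + 0.3 V) separated by gaps (ms)."""
    n_utt = len(gap_ms) + 1
    labels = labels or ["bi"] * n_utt
    anns, t = [], lead_s
    for i in range(n_utt):
        anns.append(Annotation(t, t + 0.1, t + 0.4, labels[i]))
        t += 0.4 + (gap_ms[i] / 1000.0 if i < len(gap_ms) else 0.0)
    n = int((t + lead_s) * fs)
    return SessionRecording(
        subject_id="x",
        session_id="x-0",
        sample_rate_hz=fs,
        csep=np.zeros((2, n)),
        annotations=anns,
        invalid_intervals=list(invalid),
        smc_indices=[0, 1],
    )
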