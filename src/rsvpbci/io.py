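"""Session directory serialization.

One directory per session: ``meta.json`` (rate, channel names, kind,
subject id, shape), ``signal.f32`` (row-major channels x samples,
little-endian 32-bit float), ``events.tsv`` and, for RSVP sessions,
``behavior.tsv``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Session

__all__ = ["save_session", "load_session", "validate_session_dir"]

_EVENT_COLS = ["sample", "stim_type", "trial_id", "flash_id", "character"]


def save_session(session: Session, out_dir, behavior: pd.DataFrame | None = None,
                 ) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig = np.ascontiguousarray(session.signal, dtype="<f4")
    (out / "signal.f32").write_bytes(sig.tobytes())
    meta = {
        "rate": session.rate,
        "channel_names": list(session.channel_names),
        "kind": session.kind,
        "subject_id": session.subject_id,
        "n_channels": session.n_channels,
        "n_samples": session.n_samples,
        "signal_sha256": hashlib.sha256(sig.tobytes()).hexdigest(),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    session.events[_EVENT_COLS].to_csv(out / "events.tsv", sep="\t", index=False)
    if behavior is not None:
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    return out


def load_session(in_dir) -> tuple[Session, pd.DataFrame | None]:
    """Read a session directory back; returns (session, behavior-or-None)."""
    path = Path(in_dir)
    meta = json.loads((path / "meta.json").read_text())
    sig = np.frombuffer((path / "signal.f32").read_bytes(), dtype="<f4")
    sig = sig.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    events = pd.read_csv(path / "events.tsv", sep="\t")
    session = Session(signal=sig, rate=meta["rate"],
                      channel_names=tuple(meta["channel_names"]),
                      events=events, kind=meta["kind"],
                      subject_id=meta["subject_id"])
    behavior = None
    if (path / "behavior.tsv").exists():
        behavior = pd.read_csv(path / "behavior.tsv", sep="\t",
                               keep_default_na=False,
                               dtype={"response": str})
        behavior["correct"] = behavior["correct"].astype(bool)
    return session, behavior


def validate_session_dir(in_dir) -> bool:
    """Round-trip format check: files present, shapes and hash consistent."""
    path = Path(in_dir)
    meta = json.loads((path / "meta.json").read_text())
    raw = (path / "signal.f32").read_bytes()
    if len(raw) != 4 * meta["n_channels"] * meta["n_samples"]:
        raise ValueError("signal size does not match meta")
    if hashlib.sha256(raw).hexdigest() != meta["signal_sha256"]:
        raise ValueError("signal hash mismatch")
    session, _ = load_session(path)
    session.validate()
    return True
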