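"""Session containers: the synthetic on-disk format and the published
Matlab database format.

The synthetic container is one directory holding ``iemg.npy``,
``force.npy``, ``labels.npy`` and a ``meta.json`` with the protocol, seed
and ground-truth pairing.  The Matlab loader maps container fields through a
configurable field-name dictionary, since the database schema is not fixed
here; forces recorded at a lower rate are resampled to the iEMG clock by
linear interpolation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import Movement, ProtocolSpec, SessionRecord

QUALITY_LEVELS = ("good", "questionable", "poor")

DEFAULT_MAT_FIELDS = {
    "iemg": "iEMG",
    "force": "force",
    "labels": "labels",
    "sampling_rate": "fs",
}


@dataclass
class DatabaseManifest:
    """Paths and per-channel metadata for a set of session containers."""

    files: list
    channel_quality: dict = field(default_factory=dict)  # path -> list of flags
    protocol_tag: str = "SRL"  # 'SRL' | 'LRL'
    muscles: dict = field(default_factory=dict)  # path -> list of muscle names

    def __post_init__(self) -> None:
        if self.protocol_tag not in ("SRL", "LRL"):
            raise ValueError("protocol_tag must be 'SRL' or 'LRL'")
        for path, flags in self.channel_quality.items():
            for f in flags:
                if f not in QUALITY_LEVELS:
                    raise ValueError(f"unknown quality flag {f!r} for {path}")

    @classmethod
    def from_yaml(cls, path) -> "DatabaseManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            files=list(d.get("files", [])),
            channel_quality={k: list(v) for k, v in d.get("channel_quality", {}).items()},
            protocol_tag=d.get("protocol_tag", "SRL"),
            muscles={k: list(v) for k, v in d.get("muscles", {}).items()},
        )


# ---------------------------------------------------------------------------
# synthetic container
# ---------------------------------------------------------------------------


def write_session(session: SessionRecord, path) -> None:
    """Write a session to a directory container (arrays + JSON metadata)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "iemg.npy", session.iemg)
    np.save(path / "force.npy", session.force)
    np.save(path / "labels.npy", session.labels)
    p = session.protocol
    meta = {
        "seed": session.seed,
        "protocol": {
            "sampling_rate": p.sampling_rate,
            "sine_frequency": p.sine_frequency,
            "sine_amplitude_fraction": p.sine_amplitude_fraction,
            "repetitions": p.repetitions,
            "rest_duration": p.rest_duration,
            "n_gauges": p.n_gauges,
            "movements": [dataclasses.asdict(m) for m in p.movements],
        },
        "movement_slices": {k: [int(a), int(b)] for k, (a, b) in session.movement_slices.items()},
        "ground_truth_pairing": (session.ground_truth or {}).get("pairing"),
        "channel_quality": session.channel_quality,
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def export_label_table(session: SessionRecord, path) -> None:
    """CSV of the cue labels: one row per movement with its interval bounds."""
    rows = []
    for label, (a, b) in session.movement_slices.items():
        rows.append(
            {
                "movement": label,
                "rest_start": int(a),
                "tracking_start": int(a + session.protocol.rest_samples),
                "stop": int(b),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _load_synthetic(path: Path, manifest: DatabaseManifest | None) -> SessionRecord:
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    pd_ = meta["protocol"]
    protocol = ProtocolSpec(
        sampling_rate=pd_["sampling_rate"],
        sine_frequency=pd_["sine_frequency"],
        sine_amplitude_fraction=pd_["sine_amplitude_fraction"],
        repetitions=pd_["repetitions"],
        rest_duration=pd_["rest_duration"],
        n_gauges=pd_["n_gauges"],
        movements=tuple(Movement(**m) for m in pd_["movements"]),
    )
    ground_truth = None
    if meta.get("ground_truth_pairing"):
        ground_truth = {"pairing": meta["ground_truth_pairing"]}
    quality = meta.get("channel_quality")
    if manifest is not None:
        quality = manifest.channel_quality.get(str(path), quality)
    rec = SessionRecord(
        iemg=np.load(path / "iemg.npy"),
        force=np.load(path / "force.npy"),
        labels=np.load(path / "labels.npy"),
        protocol=protocol,
        movement_slices={k: (int(a), int(b)) for k, (a, b) in meta["movement_slices"].items()},
        ground_truth=ground_truth,
        seed=meta.get("seed"),
        channel_quality=quality,
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# Matlab container
# ---------------------------------------------------------------------------


def _load_mat(path: Path, manifest: DatabaseManifest | None, field_map: dict | None,
              protocol: ProtocolSpec | None) -> SessionRecord:
    from scipy.io import loadmat

    fields = dict(DEFAULT_MAT_FIELDS)
    if field_map:
        fields.update(field_map)
    try:
        d = loadmat(path)
    except Exception as exc:  # corrupt container
        raise ValueError(f"cannot read Matlab container {path}: {exc}") from exc
    for key in ("iemg", "force"):
        if fields[key] not in d:
            raise KeyError(f"Matlab container {path} is missing field {fields[key]!r}")
    iemg = np.atleast_2d(np.asarray(d[fields["iemg"]], dtype=np.float32))
    force = np.atleast_2d(np.asarray(d[fields["force"]], dtype=np.float32))
    if iemg.shape[0] > iemg.shape[1]:
        iemg = iemg.T  # channels x samples
    if force.shape[0] > force.shape[1]:
        force = force.T
    if fields["sampling_rate"] in d:
        fs = float(np.asarray(d[fields["sampling_rate"]]).ravel()[0])
    else:
        fs = 10_000.0
        warnings.warn(f"{path}: sampling-rate field absent; defaulting to 10 kHz")
    if force.shape[1] != iemg.shape[1]:
        # force recorded (or stored) on another clock: linear interpolation
        t_new = np.linspace(0.0, 1.0, iemg.shape[1])
        t_old = np.linspace(0.0, 1.0, force.shape[1])
        force = np.vstack([np.interp(t_new, t_old, g) for g in force]).astype(np.float32)
    if fields["labels"] in d:
        labels = np.asarray(d[fields["labels"]], dtype=np.int32).ravel()
    else:
        warnings.warn(f"{path}: label field absent; session cannot be segmented")
        labels = np.full(iemg.shape[1], -1, dtype=np.int32)
    movement_slices = _slices_from_labels(labels)
    if protocol is None:
        # placeholder protocol; the real movement/gauge map comes from the
        # database's own lookup table
        protocol = ProtocolSpec(
            sampling_rate=fs,
            n_gauges=force.shape[0],
            movements=(Movement("movement_0", 0, +1),),
        )
    quality = None
    if manifest is not None:
        quality = manifest.channel_quality.get(str(path))
    return SessionRecord(
        iemg=iemg,
        force=force,
        labels=labels,
        protocol=protocol,
        movement_slices=movement_slices,
        ground_truth=None,
        seed=None,
        channel_quality=quality,
    )


def _slices_from_labels(labels: np.ndarray) -> dict:
    """Movement intervals from runs of label codes: rest for movement m is
    coded -(m+1) and precedes the tracking run coded m."""
    slices: dict[str, tuple[int, int]] = {}
    codes = np.unique(labels[labels >= 0])
    for m in codes:
        track = np.flatnonzero(labels == m)
        rest = np.flatnonzero(labels == -(m + 1))
        start = int(rest[0]) if rest.size else int(track[0])
        slices[f"movement_{m}"] = (start, int(track[-1]) + 1)
    return slices


def load_session(
    path,
    manifest: DatabaseManifest | None = None,
    field_map: dict | None = None,
    protocol: ProtocolSpec | None = None,
) -> SessionRecord:
    """Load a synthetic directory container or a Matlab ``.mat`` container.

    Channels flagged 'poor' in the manifest stay loaded but are marked so
    aggregation can exclude them.
    """
    path = Path(path)
    if path.is_dir() and (path / "meta.json").exists():
        return _load_synthetic(path, manifest)
    if path.suffix == ".mat":
        return _load_mat(path, manifest, field_map, protocol)
    raise ValueError(f"unrecognized session container: {path}")
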