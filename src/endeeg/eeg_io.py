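"""Recording I/O and 10-20 montage normalization.

Two on-disk recording formats are supported: EDF (European Data Format,
read as physical/calibrated values) and a plain "matrix-text" dialect
designed for diffable fixtures:

    Fz,Cz,Pz                <- header: comma-separated channel names
    # fs=128 subject=s01 label=adhd
    0.12,-0.4,1.0           <- one sample per row, one column per channel
    ...

Channel labels are normalized to modern 10-20 nomenclature: the older
temporal/posterior labels T3/T4/T5/T6 map to T7/T8/P7/P8 (same electrode
positions, two naming eras). Unknown labels pass through untouched — the
pipeline is montage-agnostic.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from endeeg.errors import FormatError, ValidationError

#: Old-to-modern 10-20 electrode renames (lowercase keys).
OLD_TO_MODERN = {"t3": "T7", "t4": "T8", "t5": "P7", "t6": "P8"}

#: The 19-electrode montage of a standard 10-20 clinical recording,
#: in modern nomenclature.
STANDARD_1020_19 = [
    "Fz", "Cz", "Pz", "C3", "T7", "C4", "T8", "Fp1", "Fp2",
    "F3", "F4", "F7", "F8", "P3", "P4", "P7", "P8", "O1", "O2",
]

RANKING_COLUMNS = ["channel", "H_classA", "H_classB", "EnD", "rank_end", "rank_en"]


def normalize_montage(names: list[str]) -> list[str]:
    """Map old 10-20 labels (T3/T4/T5/T6) to modern ones (T7/T8/P7/P8).

    Matching is case-insensitive; labels outside the rename table are
    returned verbatim. Idempotent.
    """
    return [OLD_TO_MODERN.get(str(n).strip().lower(), str(n).strip()) for n in names]


@dataclass
class Recording:
    """One subject's multi-channel recording.

    ``data`` has one row per channel (same order as ``channel_names``)
    and one column per sample.
    """

    subject_id: str
    label: str
    fs: float
    channel_names: list[str]
    data: np.ndarray
    normalize: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D channels x samples matrix")
        if self.normalize:
            self.channel_names = normalize_montage(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            dupes = sorted({n for n in self.channel_names if self.channel_names.count(n) > 1})
            raise ValidationError(f"duplicate channels after montage normalization: {dupes}")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Samples of one channel, looked up by (normalized) name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ValidationError(f"recording {self.subject_id!r} has no channel {name!r}") from None
        return self.data[idx]


def read_recording(
    path,
    format: str | None = None,
    subject_id: str | None = None,
    label: str | None = None,
) -> Recording:
    """Read one recording from EDF or matrix-text.

    ``format`` is ``"edf"`` or ``"matrix-text"``; when omitted it is
    inferred from the file suffix. Sample values are passed through
    unchanged (EDF is calibrated to physical units by the reader; no
    filtering or rescaling is applied). ``subject_id``/``label`` override
    whatever the file carries.
    """
    import os

    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"recording file not found: {path}")
    if format is None:
        format = "edf" if path.lower().endswith(".edf") else "matrix-text"
    if format == "edf":
        return _read_edf(path, subject_id=subject_id, label=label)
    if format == "matrix-text":
        return _read_matrix_text(path, subject_id=subject_id, label=label)
    raise ValidationError(f"unknown recording format {format!r}")


def _read_edf(path: str, subject_id: str | None, label: str | None) -> Recording:
    import os

    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for malformed files
        raise IOError(f"could not read EDF file {path}: {exc}") from exc
    return Recording(
        subject_id=subject_id or os.path.splitext(os.path.basename(path))[0],
        label=label or "unknown",
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        data=raw.get_data(),
    )


def _read_matrix_text(path: str, subject_id: str | None, label: str | None) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
        meta_line = fh.readline().strip()
        body = fh.read()
    if not header:
        raise FormatError(f"{path}: empty header line, expected channel names")
    names = [n.strip() for n in header.split(",")]
    if not meta_line.startswith("#"):
        raise FormatError(f"{path}: second line must be '# fs=<Hz> ...' metadata, got {meta_line!r}")
    meta = {}
    for tok in meta_line.lstrip("#").split():
        if "=" in tok:
            key, val = tok.split("=", 1)
            meta[key] = val
    if "fs" not in meta:
        raise FormatError(f"{path}: metadata line is missing fs=<Hz>")
    try:
        data = np.loadtxt(_stdio.StringIO(body), delimiter=",", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed sample rows: {exc}") from exc
    if data.shape[1] != len(names):
        raise FormatError(
            f"{path}: {len(names)} channels in header but {data.shape[1]} columns of samples"
        )
    return Recording(
        subject_id=subject_id or meta.get("subject", "unknown"),
        label=label or meta.get("label", "unknown"),
        fs=float(meta["fs"]),
        channel_names=names,
        data=data.T,
    )


def write_recording(rec: Recording, path) -> None:
    """Write a recording in the matrix-text dialect (value-exact round trip)."""
    with open(path, "w") as fh:
        fh.write(",".join(rec.channel_names) + "\n")
        fh.write(f"# fs={rec.fs:.17g} subject={rec.subject_id} label={rec.label}\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter=",")


def write_ranking(table: pd.DataFrame, path) -> None:
    """Persist a channel-score table as CSV at full float precision."""
    missing = [c for c in RANKING_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"ranking table is missing columns {missing}")
    table[RANKING_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_ranking(path) -> pd.DataFrame:
    """Read a ranking CSV written by :func:`write_ranking`."""
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse ranking file {path}: {exc}") from exc
    missing = [c for c in RANKING_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"ranking file {path} is missing columns {missing}")
    for col in ("rank_end", "rank_en"):
        table[col] = table[col].astype(int)
    return table


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV (columns subject_id, label, path)."""
    import os

    try:
        manifest = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse manifest {path}: {exc}") from exc
    required = {"subject_id", "label", "path"}
    if not required.issubset(manifest.columns):
        raise FormatError(f"manifest {path} must have columns {sorted(required)}")
    base = os.path.dirname(os.fspath(path))
    manifest["path"] = [
        p if os.path.isabs(p) else os.path.join(base, p) for p in manifest["path"]
    ]
    return manifest


def load_cohort(manifest: pd.DataFrame) -> list[Recording]:
    """Load every recording listed in a manifest, in manifest order."""
    return [
        read_recording(row.path, subject_id=str(row.subject_id), label=str(row.label))
        for row in manifest.itertuples()
    ]
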