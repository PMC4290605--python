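"""The 137-feature encoding of a lysine-centered window.

Feature inventory (canonical order):

* 120 positional one-hot indicators ``w-{AA}_{1..3}`` / ``w+{AA}_{1..3}``
  — one per standard amino acid per flanking slot;
* 6 per-slot Hopp–Woods hydrophilicity values ``w-{i}_Hydro`` / ``w+{i}_Hydro``;
* ``Consensus`` — window matches PsiKxE/D;
* ``wDE`` — any flanking slot holds D or E (position-unspecific acidity);
* ``wK`` — any flanking slot holds an extra lysine;
* ``Flexible`` — predicted conformational flexibility of the central K (binary);
* ``DisorderReal`` — predicted disorder tendency of the central K in [0, 1];
* ``DisorderBinary`` — disorder tendency at or above 0.5;
* ``TerminalBinary`` — central K within 10% of either terminus;
* ``SignedLength`` — protein length, negated for terminal-region sites;
* ``BeforeVol`` / ``AfterVol`` — Kharakoz volume sums of the upstream /
  downstream 3-residue sub-windows;
* ``Difference`` — ``AfterVol - BeforeVol``.

126 features are binary and 11 real-valued. Padded and non-standard slots
contribute zeros to one-hot, hydrophilicity and volume features, the
neutral value under min–max scaling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_windows import (
    PAD,
    ProteinRecord,
    SiteWindow,
    consensus_status,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

SLOT_NAMES = ("w-_1", "w-_2", "w-_3", "w+_1", "w+_2", "w+_3")

ONE_HOT_FEATURES: tuple[str, ...] = tuple(
    f"{side}{aa}_{i}" for side, i in (("w-", 1), ("w-", 2), ("w-", 3),
                                      ("w+", 1), ("w+", 2), ("w+", 3))
    for aa in AMINO_ACIDS
)
HYDRO_FEATURES: tuple[str, ...] = (
    "w-1_Hydro", "w-2_Hydro", "w-3_Hydro", "w+1_Hydro", "w+2_Hydro", "w+3_Hydro",
)
SINGLETON_FEATURES: tuple[str, ...] = (
    "Consensus", "wDE", "wK", "Flexible", "DisorderReal", "DisorderBinary",
    "TerminalBinary", "SignedLength", "BeforeVol", "AfterVol", "Difference",
)

FEATURE_NAMES: tuple[str, ...] = ONE_HOT_FEATURES + HYDRO_FEATURES + SINGLETON_FEATURES

BINARY_FEATURES: frozenset[str] = frozenset(ONE_HOT_FEATURES) | {
    "Consensus", "wDE", "wK", "Flexible", "DisorderBinary", "TerminalBinary",
}
REAL_FEATURES: tuple[str, ...] = tuple(f for f in FEATURE_NAMES if f not in BINARY_FEATURES)

#: Metadata columns accompanying the features in an encoded matrix.
META_COLUMNS = ("protein_id", "position", "label")

# Feature-count audit: 120 one-hot + 6 hydro + 11 singletons = 137,
# split 126 binary / 11 real.
assert len(FEATURE_NAMES) == 137
assert len(BINARY_FEATURES) == 126
assert len(REAL_FEATURES) == 11
assert len(set(FEATURE_NAMES)) == 137


def _load_scale(filename: str) -> dict[str, float]:
    table = {}
    with resources.files("sumosite.data").joinpath(filename).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, value = line.split("\t")
            table[aa] = float(value)
    if set(table) != set(AMINO_ACIDS):
        raise ValueError(f"{filename}: expected exactly the 20 standard amino acids")
    return table


def hopp_woods_scale() -> dict[str, float]:
    """Hopp–Woods hydrophilicity values for the 20 standard amino acids."""
    return _load_scale("hopp_woods.tsv")


def kharakoz_volumes() -> dict[str, float]:
    """Kharakoz residue partial molar volumes (cm^3/mol)."""
    return _load_scale("kharakoz_volumes.tsv")


@dataclass(frozen=True)
class FlexDisorderAnnotation:
    """Per-residue flexibility/disorder annotation for one protein.

    Produced by external predictors (conformational flexibility from
    FlexPred-style tools, disorder tendency from IUPred-style tools) or by
    the bundled synthetic generator. ``flexible`` holds 0/1 flags and
    ``disorder`` tendencies in [0, 1], both indexed so that entry ``i``
    annotates 1-based residue ``i + 1``.
    """

    protein_id: str
    flexible: tuple[int, ...]
    disorder: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.flexible) != len(self.disorder):
            raise ValueError(f"{self.protein_id}: flexible/disorder length mismatch")
        if any(f not in (0, 1) for f in self.flexible):
            raise ValueError(f"{self.protein_id}: flexible flags must be 0/1")
        if any(not (0.0 <= d <= 1.0) for d in self.disorder):
            raise ValueError(f"{self.protein_id}: disorder tendencies must lie in [0, 1]")

    def at(self, position: int) -> tuple[int, float]:
        """(flexible, disorder) at a 1-based residue position."""
        if not 1 <= position <= len(self.flexible):
            raise KeyError(
                f"annotation for protein {self.protein_id!r} does not cover "
                f"position {position}"
            )
        return self.flexible[position - 1], self.disorder[position - 1]


def null_annotation(protein: ProteinRecord) -> FlexDisorderAnnotation:
    """All-zero annotation so the pipeline runs without external predictors."""
    n = protein.length
    return FlexDisorderAnnotation(protein.id, (0,) * n, (0.0,) * n)


def read_annotations(path: str | Path) -> dict[str, FlexDisorderAnnotation]:
    """Read annotation TSV (protein_id, position, flexible, disorder)."""
    rows: dict[str, dict[int, tuple[int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, pos, flex, dis = line.split("\t")
            rows.setdefault(pid, {})[int(pos)] = (int(flex), float(dis))
    annotations = {}
    for pid, by_pos in rows.items():
        n = max(by_pos)
        if set(by_pos) != set(range(1, n + 1)):
            raise ValueError(f"{path}: annotation for {pid!r} has gaps")
        flex = tuple(by_pos[i][0] for i in range(1, n + 1))
        dis = tuple(by_pos[i][1] for i in range(1, n + 1))
        annotations[pid] = FlexDisorderAnnotation(pid, flex, dis)
    return annotations


def write_annotations(
    annotations: Mapping[str, FlexDisorderAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\tposition\tflexible\tdisorder\n")
        for pid in sorted(annotations):
            ann = annotations[pid]
            for i, (f, d) in enumerate(zip(ann.flexible, ann.disorder), 1):
                fh.write(f"{pid}\t{i}\t{f}\t{d:.6f}\n")


# ---------------------------------------------------------------------------
# Individual feature groups
# ---------------------------------------------------------------------------

def hydrophobicity_features(
    window: SiteWindow, hydro_scale: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Hopp–Woods value per flanking slot; padded/non-standard slots give 0."""
    scale = hopp_woods_scale() if hydro_scale is None else hydro_scale
    slots = window.upstream + window.downstream
    return {
        name: scale.get(residue, 0.0)
        for name, residue in zip(HYDRO_FEATURES, slots)
    }


def composition_flags(window: SiteWindow) -> tuple[int, int]:
    """(wDE, wK): position-unspecific acidity / extra-lysine presence flags."""
    flanks = window.upstream + window.downstream
    w_de = int(any(r in "DE" for r in flanks))
    w_k = int(any(r == "K" for r in flanks))
    return w_de, w_k


def terminal_and_length(position: int, length: int) -> tuple[int, int]:
    """(TerminalBinary, SignedLength) for a site.

    A site is terminal when it lies within 10% of either end; comparisons
    are exact fractional tests, no rounding. SignedLength is the protein
    length, negated for terminal sites.
    """
    if not 1 <= position <= length:
        raise ValueError(f"position {position} outside [1, {length}]")
    terminal = int(position <= 0.1 * length or position > 0.9 * length)
    return terminal, -length if terminal else length


def subwindow_volumes(
    window: SiteWindow, volume_scale: Mapping[str, float] | None = None
) -> tuple[float, float, float]:
    """(BeforeVol, AfterVol, Difference) Kharakoz sub-window volume sums."""
    scale = kharakoz_volumes() if volume_scale is None else volume_scale
    before = sum(scale.get(r, 0.0) for r in window.upstream)
    after = sum(scale.get(r, 0.0) for r in window.downstream)
    return before, after, after - before


def disorder_features(
    annotation: FlexDisorderAnnotation, position: int, cutoff: float = 0.5
) -> tuple[float, int, int]:
    """(DisorderReal, DisorderBinary, Flexible) at the central lysine.

    The binary cutoff is inclusive: tendency == cutoff maps to 1.
    """
    flexible, tendency = annotation.at(position)
    return tendency, int(tendency >= cutoff), flexible


def encode_site(
    window: SiteWindow,
    protein: ProteinRecord,
    annotation: FlexDisorderAnnotation,
    hydro_scale: Mapping[str, float] | None = None,
    volume_scale: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """All 137 features for one site, keyed by canonical feature name."""
    if window.protein_id != protein.id:
        raise ValueError(
            f"window belongs to {window.protein_id!r}, not {protein.id!r}"
        )
    hydro = hopp_woods_scale() if hydro_scale is None else hydro_scale
    volumes = kharakoz_volumes() if volume_scale is None else volume_scale

    values = dict.fromkeys(FEATURE_NAMES, 0.0)
    slots = window.upstream + window.downstream
    for slot_index, residue in enumerate(slots):
        if residue in hydro:  # standard residue, not padded
            values[ONE_HOT_FEATURES[20 * slot_index + AMINO_ACIDS.index(residue)]] = 1.0
    values.update(hydrophobicity_features(window, hydro))
    values["Consensus"] = float(consensus_status(window).is_consensus)
    w_de, w_k = composition_flags(window)
    values["wDE"], values["wK"] = float(w_de), float(w_k)
    tendency, dis_bin, flexible = disorder_features(annotation, window.position)
    values["DisorderReal"] = tendency
    values["DisorderBinary"] = float(dis_bin)
    values["Flexible"] = float(flexible)
    terminal, signed_length = terminal_and_length(window.position, protein.length)
    values["TerminalBinary"] = float(terminal)
    values["SignedLength"] = float(signed_length)
    before, after, diff = subwindow_volumes(window, volumes)
    values["BeforeVol"], values["AfterVol"], values["Difference"] = before, after, diff
    return values


def encode_dataset(
    windows: Sequence[SiteWindow],
    proteins: Sequence[ProteinRecord],
    annotations: Mapping[str, FlexDisorderAnnotation] | None = None,
    drop_features: Iterable[str] = (),
) -> pd.DataFrame:
    """Encode windows into a DataFrame of metadata + feature columns.

    When ``annotations`` is None a null (all-zero) provider is used, which
    corresponds to running without flexibility/disorder predictors.
    ``drop_features`` removes named columns after encoding (ablations).
    """
    by_id = {p.id: p for p in proteins}
    hydro = hopp_woods_scale()
    volumes = kharakoz_volumes()
    rows = []
    for w in windows:
        protein = by_id[w.protein_id]
        ann = (
            annotations[w.protein_id]
            if annotations is not None
            else null_annotation(protein)
        )
        row = {"protein_id": w.protein_id, "position": w.position, "label": w.label}
        row.update(encode_site(w, protein, ann, hydro, volumes))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))
    drop = set(drop_features)
    unknown = drop - set(FEATURE_NAMES)
    if unknown:
        raise KeyError(f"cannot drop unknown features: {sorted(unknown)}")
    return df.drop(columns=sorted(drop))


def feature_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """The feature columns of an encoded DataFrame, in canonical order."""
    cols = [c for c in df.columns if c in set(FEATURE_NAMES)]
    return df[cols]


# ---------------------------------------------------------------------------
# Min–max scaling (training-derived; test values are never clamped)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingParams:
    """Per-feature minima/maxima observed on the training matrix."""

    feature_names: tuple[str, ...]
    minima: tuple[float, ...]
    maxima: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.feature_names) == len(self.minima) == len(self.maxima)):
            raise ValueError("inconsistent scaling-parameter lengths")
        if any(hi < lo for lo, hi in zip(self.minima, self.maxima)):
            raise ValueError("scaling maximum below minimum")

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "minima": list(self.minima),
            "maxima": list(self.maxima),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(tuple(d["feature_names"]), tuple(d["minima"]), tuple(d["maxima"]))


def fit_scaler(train: pd.DataFrame) -> ScalingParams:
    """Column-wise min/max from a training feature matrix."""
    if train.empty:
        raise ValueError("cannot fit a scaler on an empty matrix")
    return ScalingParams(
        tuple(train.columns),
        tuple(float(v) for v in train.min(axis=0)),
        tuple(float(v) for v in train.max(axis=0)),
    )


def apply_scaler(params: ScalingParams, matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale to (x - min) / (max - min); constant training columns map to 0.

    Values outside the training range are deliberately not clamped, so test
    data may scale outside [0, 1].
    """
    if tuple(matrix.columns) != params.feature_names:
        missing = set(params.feature_names) - set(matrix.columns)
        extra = set(matrix.columns) - set(params.feature_names)
        raise ValueError(
            f"feature set mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    lo = np.asarray(params.minima)
    hi = np.asarray(params.maxima)
    span = hi - lo
    safe_span = np.where(span == 0, 1.0, span)
    scaled = (matrix.to_numpy(dtype=float) - lo) / safe_span
    scaled[:, span == 0] = 0.0
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def feature_codebook() -> pd.DataFrame:
    """Machine-readable table of feature name -> definition."""
    defs = {}
    for name in ONE_HOT_FEATURES:
        side = "upstream" if name.startswith("w-") else "downstream"
        aa, idx = name[2], name[-1]
        defs[name] = (
            f"1 iff {side} slot {idx} holds {aa} (binary, positional one-hot)"
        )
    for name in HYDRO_FEATURES:
        defs[name] = "Hopp-Woods hydrophilicity of the residue in this slot (real)"
    defs.update({
        "Consensus": "window matches the PsiKxE/D consensus motif (binary)",
        "wDE": "any flanking slot holds D or E, position-unspecific (binary)",
        "wK": "any flanking slot holds an extra K, position-unspecific (binary)",
        "Flexible": "central lysine predicted conformationally flexible (binary)",
        "DisorderReal": "predicted disorder tendency of the central lysine (real)",
        "DisorderBinary": "disorder tendency >= 0.5 (binary)",
        "TerminalBinary": "central lysine within 10% of either terminus (binary)",
        "SignedLength": "protein length, negated for terminal-region sites (real)",
        "BeforeVol": "Kharakoz volume sum of the upstream sub-window (real)",
        "AfterVol": "Kharakoz volume sum of the downstream sub-window (real)",
        "Difference": "AfterVol - BeforeVol (real)",
    })
    return pd.DataFrame(
        {
            "feature": list(FEATURE_NAMES),
            "kind": ["binary" if f in BINARY_FEATURES else "real" for f in FEATURE_NAMES],
            "definition": [defs[f] for f in FEATURE_NAMES],
        }
    )


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an encoded matrix (meta + features) as TSV."""
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sparse_svm(
    df: pd.DataFrame, path: str | Path, positive_label: str = "positive"
) -> None:
    """Write the sparse ``label index:value`` format used by SVM trainers.

    Indices are 1-based in canonical feature order; zero entries are omitted.
    """
    features = feature_matrix(df)
    labels = df["label"].map(lambda l: 1 if l == positive_label else -1)
    with open(path, "w") as fh:
        for (_, row), label in zip(features.iterrows(), labels):
            terms = " ".join(
                f"{i + 1}:{v:g}" for i, v in enumerate(row.to_numpy()) if v != 0
            )
            fh.write(f"{label} {terms}\n")
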