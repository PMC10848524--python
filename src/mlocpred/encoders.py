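"""Sequence descriptor groups and feature-matrix assembly.

Seven fixed-length encoders map one sequence to real-valued vectors:

========  ====  ==========================================================
group     dim   description
========  ====  ==========================================================
KMER      1360  overlapping k-mer composition, k = 2..5 (16+64+256+1024)
PSEKNC    1370  type-1 pseudo k-tuple composition: the four k-mer tiers
                plus a shared tier of lambda = 10 sequence-order
                correlation factors from dinucleotide property profiles
PSEEIIP     64  trinucleotide electron-ion interaction pseudopotentials
DPCP      2368  dinucleotide frequency x 148 physicochemical scales
TPCP       768  trinucleotide frequency x 12 physicochemical scales
ZC48        48  phase-independent Z-curve projection per dinucleotide
                prefix: (x, y, z) = purine/pyrimidine, amino/keto,
                weak/strong H-bond contrasts of trinucleotide frequencies
ZC144      144  the same projection stratified by codon phase (3 x 48)
========  ====  ==========================================================

Concatenating all groups in the fixed order KMER, PSEKNC, PSEEIIP, DPCP,
TPCP, ZC48, ZC144 yields the full 6122-column matrix.  All encoders are
pure functions of the sequence: identical input gives bit-identical
output.

The bundled di-/trinucleotide property tables are deterministic synthetic
stand-ins (z-scored per scale, see ``resources/*_synthetic.csv``); the
published scale collections are not reproduced here, and only the table
shapes (148 and 12 scales) are contractual.  Custom tables can be passed
to :func:`encode_dpcp` / :func:`encode_tpcp` or loaded with
:func:`load_property_table`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from mlocpred.seqio import LabeledRecord, NucleotideSequence

BASES = "ACGT"

DINUCLEOTIDES: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=2)
)
TRINUCLEOTIDES: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=3)
)


def oligos(k: int) -> tuple[str, ...]:
    """All 4^k oligonucleotides of length k in lexicographic order."""
    return tuple("".join(p) for p in itertools.product(BASES, repeat=k))


#: Fixed per-group output dimensions.
GROUP_DIMS: dict[str, int] = {
    "KMER": 1360,
    "PSEKNC": 1370,
    "PSEEIIP": 64,
    "DPCP": 2368,
    "TPCP": 768,
    "ZC48": 48,
    "ZC144": 144,
}

#: Column-block order used by :func:`encode_dataset`.
GROUP_ORDER: tuple[str, ...] = (
    "KMER",
    "PSEKNC",
    "PSEEIIP",
    "DPCP",
    "TPCP",
    "ZC48",
    "ZC144",
)

TOTAL_DIM = sum(GROUP_DIMS.values())  # 6122


# ---------------------------------------------------------------------------
# Property resources


@dataclass(frozen=True)
class PropertyTable:
    """Named physicochemical scales over all oligonucleotides of one length.

    ``scales`` maps scale name -> {oligo: value}; every scale must cover
    all 4^oligo_length oligonucleotides.
    """

    oligo_length: int
    scales: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        expected = set(oligos(self.oligo_length))
        for name, mapping in self.scales.items():
            missing = expected - set(mapping)
            if missing:
                raise ValueError(
                    f"scale {name!r} missing oligos: {sorted(missing)[:5]} ..."
                )

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    @property
    def scale_names(self) -> tuple[str, ...]:
        return tuple(self.scales)

    def as_array(self) -> np.ndarray:
        """(4^k oligos) x (n_scales) value matrix in canonical order."""
        olis = oligos(self.oligo_length)
        return np.array(
            [[self.scales[s][o] for s in self.scales] for o in olis],
            dtype=float,
        )


def _resource_path(name: str) -> Path:
    return Path(importlib_resources.files("mlocpred") / "resources" / name)


def load_property_table(path: str | Path) -> PropertyTable:
    """Load a property-table CSV (rows = oligos, header = scale names)."""
    df = pd.read_csv(path, index_col=0)
    k = len(str(df.index[0]))
    scales = {str(c): dict(zip(df.index.astype(str), df[c].astype(float))) for c in df.columns}
    return PropertyTable(oligo_length=k, scales=scales)


def default_dinucleotide_table() -> PropertyTable:
    """Bundled 148-scale dinucleotide table (synthetic stand-in values)."""
    return load_property_table(_resource_path("dinucleotide_scales_synthetic.csv"))


def default_trinucleotide_table() -> PropertyTable:
    """Bundled 12-scale trinucleotide table (synthetic stand-in values)."""
    return load_property_table(_resource_path("trinucleotide_scales_synthetic.csv"))


def load_eiip() -> dict[str, float]:
    """Per-nucleotide electron-ion interaction pseudopotential constants."""
    df = pd.read_csv(_resource_path("eiip.csv"))
    return dict(zip(df["base"], df["eiip"].astype(float)))


#: The six standard dinucleotide structural scales used for the PseKNC
#: sequence-order tier.
PSEKNC_SCALE_NAMES = ("Rise", "Roll", "Shift", "Slide", "Tilt", "Twist")


# ---------------------------------------------------------------------------
# Feature containers


@dataclass(frozen=True)
class FeatureVector:
    """One encoder's output for one sequence."""

    values: np.ndarray
    names: tuple[str, ...]
    group: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if self.group in GROUP_DIMS and len(self.values) != GROUP_DIMS[self.group]:
            raise ValueError(
                f"group {self.group}: expected {GROUP_DIMS[self.group]} "
                f"features, got {len(self.values)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.group}: non-finite feature values")


@dataclass
class FeatureMatrix:
    """Samples x named, group-tagged features.

    Row order matches input record order; feature names are globally
    unique (group-prefixed).
    """

    sample_ids: list[str]
    feature_names: list[str]
    feature_groups: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if len(self.feature_groups) != len(self.feature_names):
            raise ValueError("feature_groups/feature_names length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given order (names must exist)."""
        idx = {n: i for i, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in idx]
        if missing:
            raise KeyError(f"unknown feature names: {missing[:5]} ...")
        cols = [idx[n] for n in names]
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            feature_groups=[self.feature_groups[c] for c in cols],
            values=self.values[:, cols],
        )

    def write_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write matrix as TSV (first column = sample id) plus an optional
        column-metadata sidecar TSV (feature name, group)."""
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
        if sidecar is not None:
            pd.DataFrame(
                {"feature": self.feature_names, "group": self.feature_groups}
            ).to_csv(sidecar, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, sidecar: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta = pd.read_csv(sidecar, sep="\t")
        groups = dict(zip(meta["feature"], meta["group"]))
        return cls(
            sample_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
            feature_groups=[groups[str(c)] for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


# ---------------------------------------------------------------------------
# k-mer composition


def kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Counts of all overlapping k-mers; absent oligos are implicitly 0.

    The counts of a length-L sequence sum to L - k + 1.
    """
    if not 1 <= k <= 5:
        raise ValueError(f"k must be in 1..5, got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k = {k}")
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts


def _kmer_freq_array(seq: str, k: int, denom: float) -> np.ndarray:
    counts = kmer_counts(seq, k)
    olis = oligos(k)
    out = np.zeros(len(olis))
    index = {o: i for i, o in enumerate(olis)}
    for w, c in counts.items():
        out[index[w]] = c / denom
    return out


KmerNormalization = Literal["length", "per_window"]


def encode_kmer(
    seq: str, normalization: KmerNormalization = "length"
) -> FeatureVector:
    """k-mer composition for k = 2..5 (dim 1360).

    Each entry is N_i / L (count over sequence length) by default; the
    ``per_window`` mode divides by the number of windows L - k + 1
    instead, making each k-block sum to exactly 1.
    """
    if len(seq) < 5:
        raise ValueError(f"sequence length {len(seq)} < 5")
    blocks, names = [], []
    for k in range(2, 6):
        denom = len(seq) if normalization == "length" else len(seq) - k + 1
        blocks.append(_kmer_freq_array(seq, k, denom))
        names.extend(f"KMER:{o}" for o in oligos(k))
    return FeatureVector(np.concatenate(blocks), tuple(names), "KMER")


# ---------------------------------------------------------------------------
# PseKNC


def _standardized_scale_matrix(
    table: PropertyTable, scale_names: Sequence[str]
) -> np.ndarray:
    """(n_scales x 16) matrix, each scale z-scored across dinucleotides."""
    rows = []
    for name in scale_names:
        if name not in table.scales:
            raise ValueError(f"scale {name!r} not in property table")
        vals = np.array([table.scales[name][d] for d in DINUCLEOTIDES])
        sd = vals.std(ddof=0)
        if sd == 0:
            raise ValueError(f"scale {name!r} is constant")
        rows.append((vals - vals.mean()) / sd)
    return np.stack(rows)


def encode_pseknc(
    seq: str,
    lambda_: int = 10,
    w: float = 0.1,
    table: PropertyTable | None = None,
    scale_names: Sequence[str] = PSEKNC_SCALE_NAMES,
) -> FeatureVector:
    """Type-1 pseudo k-tuple nucleotide composition (dim 1370 at lambda=10).

    Four composition tiers (k = 2..5, each tier normalized by its window
    count) are followed by one shared tier of ``lambda_`` sequence-order
    correlation factors.  Correlation factor theta_j is the mean, over
    all dinucleotide pairs at lag j, of the mean squared difference of
    the six standardized structural scales.  The whole vector is jointly
    normalized by (4 + w * sum(theta)), so it sums to 1.
    """
    L = len(seq)
    if L < lambda_ + 2:
        raise ValueError(
            f"sequence length {L} too short for lambda={lambda_}; "
            f"need at least {lambda_ + 2} nt"
        )
    if table is None:
        table = default_dinucleotide_table()
    props = _standardized_scale_matrix(table, scale_names)  # scales x 16
    di_index = {d: i for i, d in enumerate(DINUCLEOTIDES)}
    di_seq = np.array([di_index[seq[i : i + 2]] for i in range(L - 1)])
    prof = props[:, di_seq]  # scales x (L-1) property profile

    thetas = np.zeros(lambda_)
    for j in range(1, lambda_ + 1):
        diffs = prof[:, :-j] - prof[:, j:]
        thetas[j - 1] = np.mean(diffs**2)

    comp_blocks, names = [], []
    for k in range(2, 6):
        comp_blocks.append(_kmer_freq_array(seq, k, L - k + 1))
        names.extend(f"PSEKNC:k{k}_{o}" for o in oligos(k))
    comp = np.concatenate(comp_blocks)  # sums to 4 (one per tier)

    denom = 4.0 + w * thetas.sum()
    values = np.concatenate([comp / denom, w * thetas / denom])
    names.extend(f"PSEKNC:lam{j}" for j in range(1, lambda_ + 1))
    # the fixed-dimension contract (1370) only applies at the default lambda
    group = "PSEKNC" if lambda_ == 10 else "PSEKNC_custom"
    return FeatureVector(values, tuple(names), group)


# ---------------------------------------------------------------------------
# Z-curve projections


def _zcurve_components(freqs: np.ndarray) -> np.ndarray:
    """Map 16x4 trinucleotide frequencies p(LM, N) to 48 components.

    For each dinucleotide prefix LM (rows), with columns (A, C, G, T):
    x = (pA + pG) - (pC + pT)   purine vs pyrimidine
    y = (pA + pC) - (pG + pT)   amino vs keto
    z = (pA + pT) - (pC + pG)   weak vs strong hydrogen bonding
    Output order: for each LM, (x, y, z).
    """
    pA, pC, pG, pT = freqs[:, 0], freqs[:, 1], freqs[:, 2], freqs[:, 3]
    x = (pA + pG) - (pC + pT)
    y = (pA + pC) - (pG + pT)
    z = (pA + pT) - (pC + pG)
    return np.stack([x, y, z], axis=1).ravel()


def _trinuc_prefix_freqs(seq: str, starts: Iterable[int], denom: int) -> np.ndarray:
    """16x4 matrix of p(LM, N) over windows at the given start offsets."""
    di_index = {d: i for i, d in enumerate(DINUCLEOTIDES)}
    base_index = {b: i for i, b in enumerate(BASES)}
    freqs = np.zeros((16, 4))
    for i in starts:
        freqs[di_index[seq[i : i + 2]], base_index[seq[i + 2]]] += 1
    if denom > 0:
        freqs /= denom
    return freqs


def _zc48_names() -> tuple[str, ...]:
    return tuple(
        f"ZC48:{c}_{d}" for d in DINUCLEOTIDES for c in ("x", "y", "z")
    )


def encode_zcurve_phase_independent(seq: str) -> FeatureVector:
    """Phase-independent Z-curve descriptor (dim 48).

    Trinucleotide frequencies are normalized by the total window count
    L - 2; every component lies in [-1, 1].
    """
    L = len(seq)
    if L < 3:
        raise ValueError(f"sequence length {L} < 3")
    freqs = _trinuc_prefix_freqs(seq, range(L - 2), L - 2)
    return FeatureVector(_zcurve_components(freqs), _zc48_names(), "ZC48")


def encode_zcurve_phase_specific(seq: str) -> FeatureVector:
    """Codon-phase-specific Z-curve descriptor (dim 144 = 3 phases x 48).

    Phase p in {1, 2, 3} collects trinucleotide windows whose start
    index is congruent to p - 1 modulo 3; frequencies are normalized
    within each phase.
    """
    L = len(seq)
    if L < 5:
        raise ValueError(f"sequence length {L} < 5")
    parts, names = [], []
    for phase in (1, 2, 3):
        starts = range(phase - 1, L - 2, 3)
        n = len(starts)
        freqs = _trinuc_prefix_freqs(seq, starts, n)
        parts.append(_zcurve_components(freqs))
        names.extend(
            f"ZC144:p{phase}_{c}_{d}" for d in DINUCLEOTIDES for c in ("x", "y", "z")
        )
    return FeatureVector(np.concatenate(parts), tuple(names), "ZC144")


# ---------------------------------------------------------------------------
# Physicochemical descriptors


def encode_pseeiip(seq: str, eiip: Mapping[str, float] | None = None) -> FeatureVector:
    """Trinucleotide electron-ion interaction pseudopotentials (dim 64).

    Feature for trinucleotide xyz = (EIIP_x + EIIP_y + EIIP_z) * f_xyz,
    with f the frequency normalized by L - 2 windows.
    """
    L = len(seq)
    if L < 3:
        raise ValueError(f"sequence length {L} < 3")
    if eiip is None:
        eiip = load_eiip()
    counts = kmer_counts(seq, 3)
    values = np.array(
        [
            (eiip[t[0]] + eiip[t[1]] + eiip[t[2]]) * counts.get(t, 0) / (L - 2)
            for t in TRINUCLEOTIDES
        ]
    )
    return FeatureVector(values, tuple(f"PSEEIIP:{t}" for t in TRINUCLEOTIDES), "PSEEIIP")


def _pcp_encode(
    seq: str, table: PropertyTable, group: str, expected_scales: int
) -> FeatureVector:
    k = table.oligo_length
    # the fixed group dimension only holds for the standard scale count;
    # custom tables (e.g. ablation probes) get an unconstrained group tag
    if table.n_scales != expected_scales:
        group = f"{group}_custom"
    L = len(seq)
    if L < k:
        raise ValueError(f"sequence length {L} < {k}")
    counts = kmer_counts(seq, k)
    olis = oligos(k)
    freqs = np.array([counts.get(o, 0) / (L - k + 1) for o in olis])
    prop = table.as_array()  # oligos x scales
    values = (freqs[:, None] * prop).ravel()  # oligo-major
    names = tuple(
        f"{group}:{o}|{s}" for o in olis for s in table.scale_names
    )
    return FeatureVector(values, names, group)


def encode_dpcp(seq: str, table: PropertyTable | None = None) -> FeatureVector:
    """Dinucleotide physicochemical properties (dim 2368 = 16 x 148).

    Feature (d, p) = f_d * P_p(d); order is oligo-major (all scales for
    AA, then all scales for AC, ...).
    """
    if table is None:
        table = default_dinucleotide_table()
    if table.oligo_length != 2:
        raise ValueError("DPCP requires a dinucleotide property table")
    return _pcp_encode(seq, table, "DPCP", 148)


def encode_tpcp(seq: str, table: PropertyTable | None = None) -> FeatureVector:
    """Trinucleotide physicochemical properties (dim 768 = 64 x 12)."""
    if table is None:
        table = default_trinucleotide_table()
    if table.oligo_length != 3:
        raise ValueError("TPCP requires a trinucleotide property table")
    return _pcp_encode(seq, table, "TPCP", 12)


# ---------------------------------------------------------------------------
# Dataset assembly


_ENCODER_BY_GROUP = {
    "KMER": lambda seq, ctx: encode_kmer(seq),
    "PSEKNC": lambda seq, ctx: encode_pseknc(seq, table=ctx["di_table"]),
    "PSEEIIP": lambda seq, ctx: encode_pseeiip(seq, eiip=ctx["eiip"]),
    "DPCP": lambda seq, ctx: encode_dpcp(seq, table=ctx["di_table"]),
    "TPCP": lambda seq, ctx: encode_tpcp(seq, table=ctx["tri_table"]),
    "ZC48": lambda seq, ctx: encode_zcurve_phase_independent(seq),
    "ZC144": lambda seq, ctx: encode_zcurve_phase_specific(seq),
}


def normalize_groups(groups: Iterable[str] | None) -> tuple[str, ...]:
    """Validate group tags (case-insensitive) and return them in the
    canonical block order."""
    if groups is None:
        return GROUP_ORDER
    requested = {g.upper() for g in groups}
    unknown = requested - set(GROUP_ORDER)
    if unknown:
        raise ValueError(
            f"unknown feature groups {sorted(unknown)}; "
            f"valid groups: {', '.join(GROUP_ORDER)}"
        )
    return tuple(g for g in GROUP_ORDER if g in requested)


def encode_sequence(
    seq: str, groups: Iterable[str] | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Encode one sequence with the selected groups (canonical order).

    Returns (values, names, group tags per feature).
    """
    sel = normalize_groups(groups)
    ctx = {
        "di_table": default_dinucleotide_table(),
        "eiip": load_eiip(),
        "tri_table": default_trinucleotide_table(),
    }
    vecs = [_ENCODER_BY_GROUP[g](seq, ctx) for g in sel]
    values = np.concatenate([v.values for v in vecs])
    names = [n for v in vecs for n in v.names]
    tags = [v.group for v in vecs for _ in v.names]
    return values, names, tags


def encode_dataset(
    records: Sequence[LabeledRecord] | Sequence[NucleotideSequence],
    groups: Iterable[str] | None = None,
) -> FeatureMatrix:
    """Encode a dataset into a samples x features matrix.

    Column blocks follow the canonical group order; with all groups
    selected the matrix has exactly 6122 columns.  A record failing an
    encoder precondition raises an error naming the record.
    """
    sel = normalize_groups(groups)
    ctx = {
        "di_table": default_dinucleotide_table(),
        "eiip": load_eiip(),
        "tri_table": default_trinucleotide_table(),
    }
    rows: list[np.ndarray] = []
    names: list[str] | None = None
    tags: list[str] | None = None
    ids: list[str] = []
    for rec in records:
        seq = rec.sequence if isinstance(rec, LabeledRecord) else rec
        try:
            vecs = [_ENCODER_BY_GROUP[g](seq.bases, ctx) for g in sel]
        except ValueError as exc:
            raise ValueError(f"record {seq.id!r}: {exc}") from exc
        rows.append(np.concatenate([v.values for v in vecs]))
        if names is None:
            names = [n for v in vecs for n in v.names]
            tags = [v.group for v in vecs for _ in v.names]
        ids.append(seq.id)
    if names is None:
        raise ValueError("no records to encode")
    return FeatureMatrix(
        sample_ids=ids,
        feature_names=names,
        feature_groups=tags,
        values=np.vstack(rows),
    )
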