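"""Sequence representation: nucleotide chemical properties plus density.

Each base is mapped to a 3-bit chemical-property triple ``(x, y, z)``:

* ``x`` — ring structure: purines (A, G) have two rings -> 1,
  pyrimidines (C, U) have one -> 0;
* ``y`` — hydrogen bonding: weak pairs (A, U) -> 1, strong pairs (G, C) -> 0;
* ``z`` — chemical functionality: amino group (A, C) -> 1, keto (G, U) -> 0.

So A -> (1,1,1), C -> (0,0,1), G -> (1,0,0), U -> (0,1,0).

On top of that, the *nucleotide density* ``d_i`` at position ``i`` is the
frequency of the base occupying position ``i`` within the prefix ending at
``i``: ``d_i = |{j <= i : n_j == n_i}| / i``.  It encodes the local
composition around the candidate site; ``d_1`` is always 1.

A window of length ``l`` is encoded position-major as
``(x_1, y_1, z_1, d_1, ..., x_l, y_l, z_l, d_l)`` — ``4 * l`` features, i.e.
164 for the default 41-nt window.  Any subset of the four channels can be
selected through a :class:`FeatureMask`, which drives the per-channel
ablation experiments.

A pseudo dinucleotide composition (PseDNC) encoder is also provided as a
baseline; its physicochemical property table is supplied by file rather
than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import AlphabetError, ParameterError
from .sequence_io import SequenceRecord, validate_window

#: Chemical-property triples (ring, hydrogen bond, functionality) per base.
NCP_TABLE: dict[str, tuple[int, int, int]] = {
    "A": (1, 1, 1),
    "C": (0, 0, 1),
    "G": (1, 0, 0),
    "U": (0, 1, 0),
}

CHANNELS = ("ring", "hbond", "functionality", "density")


def encode_ncp(base: str) -> tuple[int, int, int]:
    """Chemical-property triple (x, y, z) for one base."""
    try:
        return NCP_TABLE[base]
    except KeyError:
        raise AlphabetError(
            f"no chemical-property coordinates for {base!r}; "
            f"expected one of A, C, G, U"
        ) from None


def encode_density(seq: str) -> np.ndarray:
    """Cumulative nucleotide density, one value per position.

    ``d_i = (occurrences of seq[i] in seq[:i]) / i`` with 1-based ``i``;
    the first position is always 1.0 and every value lies in (0, 1].
    """
    if not seq:
        raise ParameterError("cannot compute density of an empty sequence")
    counts = {"A": 0, "C": 0, "G": 0, "U": 0}
    out = np.empty(len(seq))
    for i, base in enumerate(seq, start=1):
        if base not in counts:
            raise AlphabetError(f"invalid base {base!r} at position {i}")
        counts[base] += 1
        out[i - 1] = counts[base] / i
    return out


@dataclass(frozen=True)
class FeatureMask:
    """Which of the four per-position channels to emit.

    Channel order is fixed (ring, hbond, functionality, density) regardless
    of construction order, so a mask fully determines the feature layout.
    """

    channels: frozenset[str] = frozenset(CHANNELS)

    def __post_init__(self) -> None:
        bad = set(self.channels) - set(CHANNELS)
        if bad:
            raise ParameterError(
                f"unknown feature channel(s) {sorted(bad)}; "
                f"valid channels are {list(CHANNELS)}"
            )
        if not self.channels:
            raise ParameterError("feature mask must enable at least one channel")

    @classmethod
    def full(cls) -> "FeatureMask":
        return cls()

    @classmethod
    def only(cls, *channels: str) -> "FeatureMask":
        return cls(frozenset(channels))

    @property
    def ordered(self) -> tuple[str, ...]:
        return tuple(c for c in CHANNELS if c in self.channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def describe(self) -> str:
        return "+".join(self.ordered)


def encode_window(
    record: SequenceRecord,
    mask: FeatureMask | None = None,
    window_length: int | None = None,
) -> np.ndarray:
    """Encode one validated window into its numeric feature vector.

    With the full mask the vector has ``4 * l`` entries laid out
    position-major; a single-channel mask yields ``l`` entries.  When
    ``window_length`` is given the record is validated against it first
    (length + center adenosine); otherwise the record is encoded as-is,
    which unit tests use for short sequences.
    """
    if mask is None:
        mask = FeatureMask.full()
    if window_length is not None:
        validate_window(record, window_length)
    seq = record.seq
    l = len(seq)
    channels = mask.ordered
    vec = np.empty(len(channels) * l)
    density = encode_density(seq) if "density" in mask.channels else None
    for i, base in enumerate(seq):
        x, y, z = encode_ncp(base)
        values = {"ring": x, "hbond": y, "functionality": z}
        for k, ch in enumerate(channels):
            vec[i * len(channels) + k] = (
                density[i] if ch == "density" else values[ch]
            )
    return vec


def encode_dataset(
    records: Iterable[SequenceRecord],
    mask: FeatureMask | None = None,
    window_length: int | None = None,
) -> np.ndarray:
    """Stack window encodings into a 2-D feature matrix (rows = windows)."""
    rows = [encode_window(r, mask, window_length) for r in records]
    if not rows:
        n_ch = (mask or FeatureMask.full()).n_channels
        return np.empty((0, n_ch * (window_length or 0)))
    return np.vstack(rows)


def feature_matrix_frame(
    records: Sequence[SequenceRecord],
    mask: FeatureMask | None = None,
    window_length: int | None = None,
) -> pd.DataFrame:
    """Feature matrix as a DataFrame with self-describing column names.

    Columns are ``<channel>_<position>`` with 1-based positions, suitable
    for TSV/CSV export.
    """
    mask = mask or FeatureMask.full()
    X = encode_dataset(records, mask, window_length)
    if X.shape[0]:
        l = X.shape[1] // mask.n_channels
    else:
        l = window_length or 0
    columns = [
        f"{ch}_{pos}" for pos in range(1, l + 1) for ch in mask.ordered
    ]
    return pd.DataFrame(X, index=[r.id for r in records], columns=columns)


# --------------------------------------------------------------------------
# Pseudo dinucleotide composition (PseDNC) baseline
# --------------------------------------------------------------------------

DINUCLEOTIDES = tuple(a + b for a in "ACGU" for b in "ACGU")


@dataclass
class PseDNCConfig:
    """Configuration for the PseDNC baseline encoder.

    ``property_table`` maps each of the 16 dinucleotides to values of named
    physicochemical properties (e.g. enthalpy, entropy, free energy).  Each
    property is standardized to mean 0 / sd 1 across the 16 dinucleotides
    at load time.  ``lambda_`` counts the correlation tiers and ``weight_w``
    balances composition against correlation terms.
    """

    property_table: dict[str, dict[str, float]]
    lambda_: int = 2
    weight_w: float = 0.5
    _standardized: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ParameterError("lambda_ must be non-negative")
        if not 0.0 <= self.weight_w <= 1.0:
            raise ParameterError("weight_w must lie in [0, 1]")
        props = sorted({p for v in self.property_table.values() for p in v})
        if not props:
            raise ParameterError("property_table defines no properties")
        missing = [
            (dn, p)
            for dn in DINUCLEOTIDES
            for p in props
            if p not in self.property_table.get(dn, {})
        ]
        if missing:
            raise ParameterError(
                f"property_table incomplete; missing entries (first few): "
                f"{missing[:5]}"
            )
        std = {}
        for p in props:
            vals = np.array([self.property_table[dn][p] for dn in DINUCLEOTIDES])
            sd = vals.std()
            if sd == 0:
                raise ParameterError(f"property '{p}' is constant over dinucleotides")
            std[p] = (vals - vals.mean()) / sd
        object.__setattr__(self, "_standardized", std)

    @classmethod
    def from_tsv(
        cls, path: str | Path, lambda_: int = 2, weight_w: float = 0.5
    ) -> "PseDNCConfig":
        """Load a long-format TSV with columns dinucleotide, property, value."""
        df = pd.read_csv(path, sep="\t")
        expected = {"dinucleotide", "property", "value"}
        if not expected.issubset(df.columns):
            raise ParameterError(
                f"property table must have columns {sorted(expected)}, "
                f"got {list(df.columns)}"
            )
        table: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            dn = str(row["dinucleotide"]).upper().replace("T", "U")
            table.setdefault(dn, {})[str(row["property"])] = float(row["value"])
        return cls(property_table=table, lambda_=lambda_, weight_w=weight_w)


def _theta(seq: str, config: PseDNCConfig, tier: int) -> float:
    """Mean squared property distance between dinucleotides ``tier`` apart."""
    std = config._standardized
    props = list(std.keys())
    dn_index = {dn: k for k, dn in enumerate(DINUCLEOTIDES)}
    total = 0.0
    n = len(seq) - 1 - tier
    for i in range(n):
        a = dn_index[seq[i : i + 2]]
        b = dn_index[seq[i + tier : i + tier + 2]]
        total += sum((std[p][a] - std[p][b]) ** 2 for p in props) / len(props)
    return total / n


def encode_psednc(record: SequenceRecord, config: PseDNCConfig) -> np.ndarray:
    """Pseudo dinucleotide composition vector of length ``16 + lambda_``.

    The first 16 entries are dinucleotide frequencies damped by the pseudo
    components; the last ``lambda_`` entries are the weighted tier
    correlations.  All entries sum to 1 by the PseDNC normalization
    (each component divided by ``1 + w * sum(theta)``).
    """
    seq = record.seq
    l = len(seq)
    if config.lambda_ >= l - 1:
        raise ParameterError(
            f"lambda_={config.lambda_} requires sequences longer than "
            f"{config.lambda_ + 1} nt, got {l}"
        )
    freqs = np.zeros(16)
    dn_index = {dn: k for k, dn in enumerate(DINUCLEOTIDES)}
    for i in range(l - 1):
        freqs[dn_index[seq[i : i + 2]]] += 1
    freqs /= freqs.sum()
    thetas = np.array(
        [_theta(seq, config, tier) for tier in range(1, config.lambda_ + 1)]
    )
    denom = 1.0 + config.weight_w * thetas.sum()
    return np.concatenate([freqs / denom, config.weight_w * thetas / denom])
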