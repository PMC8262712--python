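"""Model-input construction: encodings, property scales, kmer windows.

Four kinds of features feed the trainable models:

- fixed-width one-hot encodings over a 22-symbol alphabet (20 standard
  residues alphabetically, then X for unknown, then a padding symbol);
- per-residue property scales (bundled canonical subset; the AAindex1 flat
  file can be loaded too) ranked by univariate selection against the labels
  (F-statistic and mutual information, at most 10 per criterion);
- odd-length kmer windows centred on an ionizable residue, padded with
  ``-`` where the window overruns a terminus;
- vectors of base-method pI predictions (19 Henderson-Hasselbalch methods)
  used as stacking input.

The peptide model consumes a 60 x 22 x 4 tensor: channel 0 one-hot
sequence, channel 1 per-residue values of the selected scales (one scale
per column), channels 2-3 scalar features (ionizable-group counts; a base
pI prediction) broadcast over dedicated column blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import IO, Mapping, Sequence

import numpy as np
from sklearn.feature_selection import f_regression, mutual_info_regression

from isopoint.charge import GROUP_ORDER, isoelectric_point, registry
from isopoint.seqio import (
    IONIZABLE_RESIDUES,
    STANDARD_AA,
    PolypeptideSequence,
)

PAD_SYMBOL = "-"
#: Fixed encoding column order: 20 standard residues, X, padding.
ENCODING_ALPHABET = STANDARD_AA + "X" + PAD_SYMBOL
N_SYMBOLS = len(ENCODING_ALPHABET)  # 22
_SYMBOL_INDEX = {ch: i for i, ch in enumerate(ENCODING_ALPHABET)}

PEPTIDE_MAX_LEN = 60
PROTEIN_MAX_LEN = 1000
KMER_SIZES = (3, 5, 7, 9, 11, 13, 15)


@dataclass(frozen=True)
class PropertyScaleTable:
    """One numerical amino-acid property scale (20 standard residues)."""

    scale_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_AA):
            raise ValueError(
                f"scale {self.scale_id!r} must define exactly the 20 standard residues"
            )

    @property
    def usable(self) -> bool:
        """Constant scales carry no information and are flagged unusable."""
        vals = list(self.values.values())
        return max(vals) > min(vals) and all(np.isfinite(vals))

    def value_of(self, residue: str, default: float = 0.0) -> float:
        return float(self.values.get(residue, default))

    def sequence_mean(self, sequence: str) -> float:
        """Mean scale value over residues (X and pads contribute nothing)."""
        vals = [self.values[ch] for ch in sequence if ch in self.values]
        return float(np.mean(vals)) if vals else 0.0


@dataclass(frozen=True)
class KmerWindow:
    """An odd-length window centred on an ionizable residue (or a terminus)."""

    centre: int  # 1-based position in the parent sequence
    centre_residue: str
    k: int
    residues: str  # window of length k, PAD_SYMBOL beyond chain ends

    def __post_init__(self) -> None:
        if len(self.residues) != self.k:
            raise ValueError("window length must equal k")


def load_bundled_scales() -> dict[str, PropertyScaleTable]:
    """The canonical property scales shipped with the package."""
    raw = json.loads(
        resources.files("isopoint.data").joinpath("property_scales.json").read_text()
    )
    return {
        sid: PropertyScaleTable(scale_id=sid, values=vals)
        for sid, vals in raw["scales"].items()
    }


def read_aaindex1(source: IO[str] | str) -> dict[str, PropertyScaleTable]:
    """Parse an AAindex1 flat file (H/I record lines) into scale tables.

    Records with missing (``NA``) values are skipped. The two I-line value
    rows follow the standard residue order A R N D C Q E G H I /
    L K M F P S T W Y V.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    order = "ARNDCQEGHI" + "LKMFPSTWYV"
    scales: dict[str, PropertyScaleTable] = {}
    current_id: str | None = None
    collecting = 0
    values: list[str] = []
    for line in text.splitlines():
        if line.startswith("H "):
            current_id = line[2:].strip()
        elif line.startswith("I "):
            collecting = 2
            values = []
        elif collecting > 0:
            values.extend(line.split())
            collecting -= 1
            if collecting == 0 and current_id is not None:
                if len(values) == 20 and "NA" not in values:
                    scales[current_id] = PropertyScaleTable(
                        scale_id=current_id,
                        values={aa: float(v) for aa, v in zip(order, values)},
                    )
                current_id = None
    return scales


def one_hot_encode(
    seq: PolypeptideSequence | str, max_len: int = PEPTIDE_MAX_LEN
) -> np.ndarray:
    """(max_len, 22) one-hot matrix; right-padded or right-truncated.

    Every row is exactly one-hot: padded rows are hot on the PAD column.
    """
    residues = seq.residues if isinstance(seq, PolypeptideSequence) else seq
    residues = residues[:max_len]
    mat = np.zeros((max_len, N_SYMBOLS))
    for i, ch in enumerate(residues):
        mat[i, _SYMBOL_INDEX[ch]] = 1.0
    mat[len(residues):, _SYMBOL_INDEX[PAD_SYMBOL]] = 1.0
    return mat


@dataclass(frozen=True)
class ScaleSelection:
    """Result of univariate scale selection against a labelled dataset."""

    ids: tuple[str, ...]  # union, F-ranked first then new MI-ranked entries
    f_ranking: tuple[tuple[str, float], ...]
    mi_ranking: tuple[tuple[str, float], ...]


def select_informative_scales(
    tables: Mapping[str, PropertyScaleTable],
    dataset,
    k: int = 10,
    seed: int = 0,
) -> ScaleSelection:
    """Rank scales by univariate relevance of their per-sequence means.

    Each scale is reduced to one feature per sequence (mean over residues),
    then scored by the regression F-statistic and by mutual information
    against the labels. The union of the top-k under each criterion is
    returned; ``k`` is capped at 10 per criterion.
    """
    if len(dataset) < 20:
        raise ValueError("need at least 20 records for scale selection")
    k = min(k, 10)
    usable = {sid: t for sid, t in tables.items() if t.usable}
    if not usable:
        raise ValueError("no usable (non-constant) scales")
    ids = list(usable)
    X = np.array(
        [[usable[sid].sequence_mean(s) for sid in ids] for s in dataset.sequences]
    )
    y = dataset.values
    f_scores, _ = f_regression(X, y)
    f_scores = np.nan_to_num(f_scores, nan=0.0)
    mi_scores = mutual_info_regression(X, y, random_state=seed)
    f_rank = sorted(zip(ids, f_scores), key=lambda t: -t[1])[:k]
    mi_rank = sorted(zip(ids, mi_scores), key=lambda t: -t[1])[:k]
    union = [sid for sid, _ in f_rank]
    union += [sid for sid, _ in mi_rank if sid not in union]
    return ScaleSelection(
        ids=tuple(union),
        f_ranking=tuple((sid, float(s)) for sid, s in f_rank),
        mi_ranking=tuple((sid, float(s)) for sid, s in mi_rank),
    )


def kmer_window(
    seq: PolypeptideSequence | str,
    centre: int,
    k: int,
    terminus_mode: bool = False,
) -> KmerWindow:
    """Symmetric window of odd size ``k`` centred on 1-based ``centre``.

    The centre must be an ionizable residue (C, D, E, H, K, R, Y) unless
    ``terminus_mode`` is set (used for the alpha-amino / alpha-carboxyl
    sites at positions 1 and L). Overruns past either terminus are filled
    with the ``-`` pad symbol.
    """
    residues = seq.residues if isinstance(seq, PolypeptideSequence) else seq
    if k % 2 == 0 or not (3 <= k <= 15):
        raise ValueError(f"k must be odd and within [3, 15], got {k}")
    if not (1 <= centre <= len(residues)):
        raise ValueError(f"centre {centre} outside sequence of length {len(residues)}")
    centre_res = residues[centre - 1]
    if centre_res not in IONIZABLE_RESIDUES and not terminus_mode:
        raise ValueError(
            f"centre residue {centre_res!r} at position {centre} is not ionizable"
        )
    h = k // 2
    chars = []
    for pos in range(centre - h, centre + h + 1):
        if 1 <= pos <= len(residues):
            chars.append(residues[pos - 1])
        else:
            chars.append(PAD_SYMBOL)
    return KmerWindow(centre=centre, centre_residue=centre_res, k=k,
                      residues="".join(chars))


def default_base_methods() -> tuple[str, ...]:
    """The 19 Henderson-Hasselbalch base methods, in fixed registry order."""
    return tuple(sorted(registry()))


def base_method_vector(
    seq: PolypeptideSequence,
    method_names: Sequence[str] | None = None,
) -> np.ndarray:
    """pI predictions of the configured base methods, in the given order."""
    names = tuple(method_names) if method_names is not None else default_base_methods()
    reg = registry()
    missing = [n for n in names if n not in reg]
    if missing:
        raise KeyError(f"unknown base methods {missing}; available: {sorted(reg)}")
    return np.array([isoelectric_point(seq, reg[n]) for n in names])


def encode_kmer_window(
    window: KmerWindow,
    scales: Sequence[PropertyScaleTable] = (),
    site_type: str | None = None,
) -> np.ndarray:
    """Flat feature vector for one kmer window.

    Concatenates the flattened one-hot window (k x 22), per-scale features
    (value at the centre residue and mean over the window) and, when
    ``site_type`` is given, a one-hot site-type block over the nine
    ionizable groups.
    """
    mat = np.zeros((window.k, N_SYMBOLS))
    for i, ch in enumerate(window.residues):
        mat[i, _SYMBOL_INDEX[ch]] = 1.0
    parts = [mat.ravel()]
    for scale in scales:
        centre_val = scale.value_of(window.centre_residue)
        window_vals = [scale.values[c] for c in window.residues if c in scale.values]
        mean_val = float(np.mean(window_vals)) if window_vals else 0.0
        parts.append(np.array([centre_val, mean_val]))
    if site_type is not None:
        block = np.zeros(len(GROUP_ORDER))
        block[GROUP_ORDER.index(site_type)] = 1.0
        parts.append(block)
    return np.concatenate(parts)


def build_peptide_tensor(
    seq: PolypeptideSequence,
    selected_scales: Sequence[PropertyScaleTable],
    counts: Sequence[float],
    base_pi: float,
) -> np.ndarray:
    """The (60, 22, 4) multichannel peptide input tensor.

    Channel 0: one-hot sequence. Channel 1: column ``j`` holds the per-residue
    values of selected scale ``j`` (at most 22 scales; X and pad rows are 0).
    Channel 2: the nine ionizable-group counts broadcast down columns 0-8.
    Channel 3: the base-method pI prediction broadcast down column 0.
    """
    if seq.length > PEPTIDE_MAX_LEN:
        raise ValueError(
            f"peptide longer than {PEPTIDE_MAX_LEN} residues ({seq.length}); "
            "use the protein pathway"
        )
    if len(selected_scales) > N_SYMBOLS:
        raise ValueError(f"at most {N_SYMBOLS} scales fit the channel")
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(GROUP_ORDER),):
        raise ValueError(f"counts must have {len(GROUP_ORDER)} entries")
    tensor = np.zeros((PEPTIDE_MAX_LEN, N_SYMBOLS, 4))
    tensor[:, :, 0] = one_hot_encode(seq, PEPTIDE_MAX_LEN)
    for j, scale in enumerate(selected_scales):
        for i, ch in enumerate(seq.residues):
            tensor[i, j, 1] = scale.value_of(ch)
    tensor[:, : len(GROUP_ORDER), 2] = counts
    tensor[:, 0, 3] = base_pi
    return tensor
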