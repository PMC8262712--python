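"""pH-dependent net charge and isoelectric point via Henderson-Hasselbalch.

The net charge of a polypeptide at a given pH is the sum over its ionizable
groups of the Henderson-Hasselbalch protonation fractions:

    Q(pH) =  sum_basic  n_g / (1 + 10^(pH - pKa_g))
           - sum_acidic n_g / (1 + 10^(pKa_g - pH))

Basic groups: alpha-amino terminus, His, Lys, Arg. Acidic groups:
alpha-carboxyl terminus, Cys, Asp, Glu, Tyr. Q is strictly decreasing in pH,
so the isoelectric point (the root of Q) is unique and found by bisection.

A :class:`PKaSet` names one assignment of dissociation constants to the nine
groups. The registry ships the published sets commonly benchmarked against
each other (EMBOSS, Grimsley, Bjellqvist/ExPASy, ProMoST, ...). Bjellqvist
and ProMoST are position-aware: the pKa of a group depends on whether its
residue sits at a chain terminus, and the terminal alpha-group pKa depends
on the terminal residue identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from isopoint.seqio import (
    IONIZABLE_RESIDUES,
    IonizableComposition,
    PolypeptideSequence,
    ionizable_composition,
)

#: Canonical order of the nine ionizable groups used by vectorized code.
GROUP_ORDER = ("n_term", "c_term", "C", "D", "E", "H", "K", "R", "Y")
BASIC_GROUPS = frozenset({"n_term", "H", "K", "R"})
ACIDIC_GROUPS = frozenset({"c_term", "C", "D", "E", "Y"})
#: +1 for basic groups, -1 for acidic, aligned with GROUP_ORDER.
GROUP_SIGNS = np.array([1 if g in BASIC_GROUPS else -1 for g in GROUP_ORDER])


class UnknownPKaSetError(KeyError):
    """Raised when a pKa set name is not in the registry."""


@dataclass(frozen=True)
class PKaSet:
    """A named assignment of pKa values to the nine ionizable groups.

    ``side_chain`` may omit a residue, meaning the group is treated as
    non-titratable under this set (e.g. Patrickios ignores C, H and Y).
    Position-aware sets additionally carry:

    - ``n_term_by_residue`` / ``c_term_by_residue``: alpha-group pKa keyed by
      the identity of the terminal residue (fallback: ``n_term``/``c_term``);
    - ``side_chain_positional``: per-group overrides keyed by context
      ``"n_term"`` / ``"c_term"`` for side chains sitting at a terminus.
    """

    name: str
    n_term: float
    c_term: float
    side_chain: Mapping[str, float]
    n_term_by_residue: Mapping[str, float] = field(default_factory=dict)
    c_term_by_residue: Mapping[str, float] = field(default_factory=dict)
    side_chain_positional: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = [self.n_term, self.c_term, *self.side_chain.values()]
        values += list(self.n_term_by_residue.values())
        values += list(self.c_term_by_residue.values())
        for ctx in self.side_chain_positional.values():
            values += list(ctx.values())
        for v in values:
            if not (0.0 < v < 14.0):
                raise ValueError(f"pKa set {self.name!r}: value {v} outside (0, 14)")
        unknown = set(self.side_chain) - set(IONIZABLE_RESIDUES)
        if unknown:
            raise ValueError(f"pKa set {self.name!r}: non-ionizable side chains {unknown}")

    @property
    def position_aware(self) -> bool:
        return bool(self.n_term_by_residue or self.c_term_by_residue
                    or self.side_chain_positional)

    def as_vector(self) -> np.ndarray:
        """Nine pKa values in GROUP_ORDER; NaN for non-titratable groups."""
        vec = [self.n_term, self.c_term]
        vec += [self.side_chain.get(g, np.nan) for g in GROUP_ORDER[2:]]
        return np.array(vec, dtype=float)

    @classmethod
    def from_vector(cls, name: str, vector: np.ndarray) -> "PKaSet":
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (9,):
            raise ValueError(f"expected 9 pKa values, got shape {vector.shape}")
        side = {g: float(v) for g, v in zip(GROUP_ORDER[2:], vector[2:]) if np.isfinite(v)}
        return cls(name=name, n_term=float(vector[0]), c_term=float(vector[1]),
                   side_chain=side)


@dataclass(frozen=True)
class ChargeProfile:
    """Net charge evaluated on an ascending pH grid."""

    ph: np.ndarray
    charge: np.ndarray

    def __post_init__(self) -> None:
        if self.ph.shape != self.charge.shape:
            raise ValueError("pH grid and charge arrays must align")


def _sequence_terms(
    seq: PolypeptideSequence, pka: PKaSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pKa, sign, count) arrays for every ionizable group of a sequence.

    Resolves positional overrides, so this is the single source of truth for
    position-aware sets.
    """
    pkas: list[float] = []
    signs: list[int] = []
    res = seq.residues
    first, last = res[0], res[-1]
    # Alpha-amino / alpha-carboxyl groups, terminal-residue aware.
    pkas.append(pka.n_term_by_residue.get(first, pka.n_term))
    signs.append(1)
    pkas.append(pka.c_term_by_residue.get(last, pka.c_term))
    signs.append(-1)
    n = len(res)
    for i, ch in enumerate(res):
        if ch not in pka.side_chain:
            continue
        value = pka.side_chain[ch]
        ctx = pka.side_chain_positional.get(ch, {})
        if i == 0 and "n_term" in ctx:
            value = ctx["n_term"]
        elif i == n - 1 and "c_term" in ctx:
            value = ctx["c_term"]
        pkas.append(value)
        signs.append(1 if ch in BASIC_GROUPS else -1)
    return (np.array(pkas), np.array(signs), np.ones(len(pkas)))


def _composition_terms(
    comp: IonizableComposition, pka: PKaSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pkas = [pka.n_term, pka.c_term]
    signs = [1, -1]
    counts = [1.0, 1.0]
    for g in GROUP_ORDER[2:]:
        if g not in pka.side_chain:
            continue
        c = comp.side_chain_count(g)
        if c:
            pkas.append(pka.side_chain[g])
            signs.append(1 if g in BASIC_GROUPS else -1)
            counts.append(float(c))
    return np.array(pkas), np.array(signs), np.array(counts)


def _terms(
    molecule: IonizableComposition | PolypeptideSequence, pka: PKaSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(molecule, PolypeptideSequence):
        if pka.position_aware:
            return _sequence_terms(molecule, pka)
        return _composition_terms(ionizable_composition(molecule), pka)
    if pka.position_aware:
        raise TypeError(
            f"pKa set {pka.name!r} is position-aware; pass the full sequence, "
            "not a composition"
        )
    return _composition_terms(molecule, pka)


def _charge_from_terms(pkas, signs, counts, ph):
    ph = np.asarray(ph, dtype=float)
    scalar = ph.ndim == 0
    ph2 = np.atleast_1d(ph)[:, None]
    # Basic: n/(1+10^(pH-pKa)); acidic: -n/(1+10^(pKa-pH)).
    delta = np.where(signs > 0, ph2 - pkas, pkas - ph2)
    q = np.sum(signs * counts / (1.0 + 10.0 ** delta), axis=1)
    return float(q[0]) if scalar else q


def net_charge(
    molecule: IonizableComposition | PolypeptideSequence,
    pH: float,
    pka: PKaSet,
) -> float:
    """Net charge (elementary units) at ``pH`` under pKa set ``pka``.

    Accepts either an :class:`IonizableComposition` (order-free sets) or a
    full :class:`PolypeptideSequence` (required for position-aware sets).
    """
    ph_arr = np.asarray(pH, dtype=float)
    if np.any(ph_arr < 0.0) or np.any(ph_arr > 14.0):
        raise ValueError(f"pH {pH} outside [0, 14]")
    return _charge_from_terms(*_terms(molecule, pka), ph_arr)


def isoelectric_point(
    seq: PolypeptideSequence | IonizableComposition,
    pka: PKaSet,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> float:
    """Isoelectric point: the unique root of the net charge on [0, 14].

    Solved by bisection (Q is strictly monotone decreasing, so the root is
    unique); ``tol`` is the bracket half-width at termination, in pH units.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pkas, signs, counts = _terms(seq, pka)
    lo, hi = 0.0, 14.0
    q_lo = _charge_from_terms(pkas, signs, counts, lo)
    q_hi = _charge_from_terms(pkas, signs, counts, hi)
    if q_lo < 0 or q_hi > 0:
        raise ValueError(
            f"net charge does not change sign on [0, 14] (Q(0)={q_lo:.3g}, "
            f"Q(14)={q_hi:.3g}); molecule lacks an acidic or basic group"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if _charge_from_terms(pkas, signs, counts, mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol:
            break
    return 0.5 * (lo + hi)


def charge_profile(
    seq: PolypeptideSequence | IonizableComposition,
    pka: PKaSet,
    step: float = 0.1,
) -> ChargeProfile:
    """Net charge evaluated on a regular pH grid over [0, 14]."""
    if step <= 0:
        raise ValueError("grid step must be positive")
    grid = np.arange(0.0, 14.0 + step / 2, step)
    grid = np.clip(grid, 0.0, 14.0)
    q = _charge_from_terms(*_terms(seq, pka), grid)
    return ChargeProfile(ph=grid, charge=q)


_REGISTRY_CACHE: dict[str, PKaSet] | None = None


def _load_registry() -> dict[str, PKaSet]:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        raw = json.loads(
            resources.files("isopoint.data").joinpath("pka_sets.json").read_text()
        )
        _REGISTRY_CACHE = {
            name: PKaSet(
                name=name,
                n_term=entry["n_term"],
                c_term=entry["c_term"],
                side_chain=entry["side_chain"],
                n_term_by_residue=entry.get("n_term_by_residue", {}),
                c_term_by_residue=entry.get("c_term_by_residue", {}),
                side_chain_positional=entry.get("side_chain_positional", {}),
            )
            for name, entry in raw["sets"].items()
        }
    return _REGISTRY_CACHE


def registry() -> dict[str, PKaSet]:
    """All bundled pKa sets, name -> :class:`PKaSet` (a fresh dict copy)."""
    return dict(_load_registry())


def get_pka_set(name: str) -> PKaSet:
    """Look up one registered pKa set by name."""
    reg = _load_registry()
    try:
        return reg[name]
    except KeyError:
        raise UnknownPKaSetError(
            f"unknown pKa set {name!r}; available: {', '.join(sorted(reg))}"
        ) from None
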