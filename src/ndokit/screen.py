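"""Non-Aufbau pair screening over fragment frontier levels.

When the HOMO of one isolated fragment lies above the LUMO of another,
bringing the two together (even at non-interacting distance) admits a
non-Aufbau-filled SCF solution, and energy minimization will instead
delocalize charge across the pair.  Screening all ordered (donor,
acceptor) pairs of a level table therefore predicts which combinations a
given functional renders problematic, without running any supersystem
calculation.

Conventions: the gap of a pair is eps_LUMO(acceptor) - eps_HOMO(donor) in
eV; a pair is flagged when the gap is strictly negative.  By default,
ordered pairs of *distinct* species only are screened (records sharing an
amino_acid label are skipped), and records from different functionals are
never compared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd


class ComparabilityError(ValueError):
    """Levels computed with different functionals were compared."""


@dataclass(frozen=True)
class FrontierLevels:
    """Frontier-orbital record of one fragment in one charge state.

    Energies are in eV.  amino_acid is an optional parent-species label
    used by the pair-exclusion rule (fragment_id is unique per record,
    amino_acid groups its charge states).
    """

    fragment_id: str
    charge: int
    homo_ev: float
    lumo_ev: float
    functional: str = "unspecified"
    amino_acid: Optional[str] = None

    def __post_init__(self):
        if not (np.isfinite(self.homo_ev) and np.isfinite(self.lumo_ev)):
            raise ValueError(f"non-finite level in {self.fragment_id!r}")

    @property
    def species(self) -> str:
        return self.amino_acid if self.amino_acid is not None \
            else self.fragment_id


def pair_gap(donor: FrontierLevels, acceptor: FrontierLevels,
             allow_cross_functional=False) -> float:
    """eps_LUMO(acceptor) - eps_HOMO(donor) in eV; negative = non-Aufbau."""
    if donor.functional != acceptor.functional and not allow_cross_functional:
        raise ComparabilityError(
            f"levels from different functionals ({donor.functional!r} vs "
            f"{acceptor.functional!r}); pass allow_cross_functional=True "
            "to override")
    return acceptor.lumo_ev - donor.homo_ev


@dataclass
class PairScreenResult:
    """Flagged ordered pairs and their charge-state breakdown.

    counts is a (Q_d x Q_a) DataFrame; total equals len(flagged); every
    flagged pair has gap < 0.
    """

    flagged: list  # (donor_id, acceptor_id, gap_ev)
    counts: pd.DataFrame
    functional: str = "unspecified"

    @property
    def total(self) -> int:
        return len(self.flagged)

    def to_dict(self) -> dict:
        return {
            "functional": self.functional,
            "total": self.total,
            "counts": {str(qd): {str(qa): int(self.counts.loc[qd, qa])
                                 for qa in self.counts.columns}
                       for qd in self.counts.index},
            "flagged": [(d, a, g) for d, a, g in self.flagged],
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def exclusion_rule(name: str) -> Callable[[FrontierLevels, FrontierLevels], bool]:
    """Named pair-exclusion rules; returns True when a pair is screened.

    'distinct-species': ordered pairs of different species only (records
    sharing an amino_acid label are skipped, including a record with
    itself).  'none': all ordered pairs of distinct records.
    """
    if name == "distinct-species":
        return lambda d, a: d.species != a.species
    if name == "none":
        return lambda d, a: d is not a
    raise ValueError(f"unknown exclusion rule {name!r}")


def screen_pairs(levels: Sequence[FrontierLevels],
                 exclusion="distinct-species",
                 allow_cross_functional=False) -> PairScreenResult:
    """Flag every admissible ordered (donor, acceptor) pair with gap < 0.

    The count matrix is indexed by (Q_d, Q_a) over all charge states
    present in the table.  Strict inequality: a exactly vanishing gap is
    not flagged.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least two records to screen pairs")
    functionals = {r.functional for r in levels}
    if len(functionals) > 1 and not allow_cross_functional:
        raise ComparabilityError(
            f"table mixes functionals {sorted(functionals)}; screen each "
            "separately (see summarize_by_functional) or override")
    rule = exclusion_rule(exclusion) if isinstance(exclusion, str) else exclusion
    charges = sorted({r.charge for r in levels})
    counts = pd.DataFrame(0, index=charges, columns=charges, dtype=int)
    counts.index.name = "Q_d"
    counts.columns.name = "Q_a"
    flagged = []
    for d in levels:
        for a in levels:
            if d is a or not rule(d, a):
                continue
            gap = pair_gap(d, a, allow_cross_functional=True)
            if gap < 0.0:
                flagged.append((d.fragment_id, a.fragment_id, float(gap)))
                counts.loc[d.charge, a.charge] += 1
    functional = levels[0].functional if len(functionals) == 1 else "mixed"
    return PairScreenResult(flagged=flagged, counts=counts,
                            functional=functional)


def summarize_by_functional(results: dict) -> pd.DataFrame:
    """Combine {functional: PairScreenResult} into one tidy table.

    One row per functional, sorted by descending total; per-cell counts in
    columns named 'Qd_{qd}/Qa_{qa}'.
    """
    rows = []
    for name, res in results.items():
        row = {"functional": name, "total": res.total}
        for qd in res.counts.index:
            for qa in res.counts.columns:
                row[f"Qd_{qd:+d}/Qa_{qa:+d}"] = int(res.counts.loc[qd, qa])
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["functional", "total"])
    df = pd.DataFrame(rows).fillna(0)
    value_cols = [c for c in df.columns if c != "functional"]
    df[value_cols] = df[value_cols].astype(int)
    return df.sort_values(["total", "functional"],
                          ascending=[False, True]).reset_index(drop=True)
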