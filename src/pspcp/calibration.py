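"""Grid calibration of (w, lambda) and nested (gamma, C) by jackknife accuracy.

The outer grid enumerates the descriptor parameters: w from 0.05 to 1.00 in
steps of 0.05 (20 values) and lambda from 2 to 20 (19 values), 380
combinations.  For each combination an inner grid over the SVM parameters
(powers of two, the canonical libsvm search ranges: gamma in 2^-15..2^3,
C in 2^-5..2^15) is searched, and the jackknife overall accuracy of the best
inner point is recorded.  The winner is the global accuracy argmax; ties are
broken toward the simplest model (smallest lambda, then w, then C, then
gamma).

Note w = 1.00 sits inside the enumeration range although user-facing feature
configs require w strictly inside (0, 1); the calibration loop therefore
assembles descriptors directly rather than through ``FeatureConfig``.
Composition and pseudofactors depend only on lambda, so they are computed
once per lambda and re-weighted cheaply for each w.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledDataset
from .evaluation import jackknife
from .features import assemble_descriptor, composition, pseudofactors, pspcp
from .classifier import ModelConfig
from .properties import NormalizedPropertyTable, default_property_table

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised for empty or infeasible calibration grids."""


@dataclass(frozen=True)
class CalibrationGrid:
    """Search grids for w, lambda, gamma and C."""

    w_values: tuple[float, ...]
    lambda_values: tuple[int, ...]
    gamma_values: tuple[float, ...]
    C_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("w_values", "lambda_values", "gamma_values", "C_values"):
            vals = tuple(getattr(self, name))
            if not vals:
                raise CalibrationError(f"{name} is empty")
            object.__setattr__(self, name, vals)
        if any(not (0 < w <= 1) for w in self.w_values):
            raise CalibrationError("w values must lie in (0, 1]")
        if any(lam < 1 for lam in self.lambda_values):
            raise CalibrationError("lambda values must be positive integers")
        if any(g <= 0 for g in self.gamma_values) or any(
            c <= 0 for c in self.C_values
        ):
            raise CalibrationError("gamma and C values must be positive")


def default_grid() -> CalibrationGrid:
    """The default calibration grid.

    w: 0.05..1.00 step 0.05; lambda: 2..20 step 1 (380 outer combinations);
    gamma: 2^-15..2^3; C: 2^-5..2^15 (the canonical libsvm grid-search
    ranges).
    """
    return CalibrationGrid(
        w_values=tuple(round(0.05 * i, 2) for i in range(1, 21)),
        lambda_values=tuple(range(2, 21)),
        gamma_values=tuple(2.0**e for e in range(-15, 4)),
        C_values=tuple(2.0**e for e in range(-5, 16)),
    )


@dataclass(frozen=True)
class CombinationRecord:
    """Best inner-grid result for one (w, lambda) combination."""

    w: float
    lam: int
    gamma: float
    C: float
    acc: float


@dataclass
class CalibrationResult:
    """All combination records plus the winning parameter set."""

    records: list[CombinationRecord]
    winner: CombinationRecord
    ties: list[CombinationRecord] = field(default_factory=list)
    infeasible: list[tuple[float, int, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "winner": vars(self.winner),
            "ties": [vars(t) for t in self.ties],
            "n_records": len(self.records),
            "infeasible": [
                {"w": w, "lambda": lam, "reason": reason}
                for w, lam, reason in self.infeasible
            ],
        }


def _tie_key(rec: CombinationRecord) -> tuple:
    return (rec.lam, rec.w, rec.C, rec.gamma)


def calibrate(
    dataset: LabeledDataset,
    grid: CalibrationGrid | None = None,
    props: NormalizedPropertyTable | None = None,
) -> CalibrationResult:
    """Exhaustive grid calibration maximizing jackknife overall accuracy.

    Lambda values not smaller than the shortest sequence are infeasible;
    they are skipped with a logged reason and reported in the result, never
    silently dropped.  Deterministic for fixed inputs.
    """
    if grid is None:
        grid = default_grid()
    if props is None:
        props = default_property_table()
    profiles = dataset.profiles
    if profiles is None:
        from .profiles import load_profiles

        profiles = load_profiles(dataset.records, None)
    y = list(dataset.labels)
    min_len = dataset.min_length

    d_mats = [pspcp(p, props) for p in profiles]
    f_vecs = [composition(p) for p in profiles]

    records: list[CombinationRecord] = []
    infeasible: list[tuple[float, int, str]] = []
    for lam in grid.lambda_values:
        if lam >= min_len:
            reason = f"lambda={lam} >= shortest sequence length {min_len}"
            logger.warning("skipping infeasible lambda: %s", reason)
            for w in grid.w_values:
                infeasible.append((w, lam, reason))
            continue
        u_mats = [pseudofactors(d, lam) for d in d_mats]
        for w in grid.w_values:
            X = np.vstack(
                [
                    assemble_descriptor(f, u, w)
                    for f, u in zip(f_vecs, u_mats)
                ]
            )
            best: CombinationRecord | None = None
            # inner grid: smallest C then gamma wins ties
            for C in grid.C_values:
                for gamma in grid.gamma_values:
                    report = jackknife(
                        X, y, model_config=ModelConfig(gamma=gamma, C=C)
                    )
                    acc = report.overall_acc
                    if best is None or acc > best.acc:
                        best = CombinationRecord(w, lam, gamma, C, acc)
            records.append(best)
    if not records:
        raise CalibrationError(
            "no feasible (w, lambda) combinations for this dataset"
        )
    best_acc = max(r.acc for r in records)
    contenders = sorted(
        (r for r in records if r.acc == best_acc), key=_tie_key
    )
    winner = contenders[0]
    ties = contenders[1:]
    return CalibrationResult(records, winner, ties, infeasible)


def write_calibration_tsv(result: CalibrationResult, path) -> None:
    """One row per (w, lambda) combination: w, lambda, best gamma, best C, ACC."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("w\tlambda\tgamma\tC\tjackknife_acc\n")
        for rec in result.records:
            fh.write(
                f"{rec.w:g}\t{rec.lam}\t{rec.gamma:g}\t{rec.C:g}\t{rec.acc:.17g}\n"
            )
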