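"""Synthetic labeled sequences with matching PSSMs and tunable class signal.

The generator emulates the two information channels the descriptor scheme is
built to capture, without any claim of biological realism:

* a composition channel: each class tilts its residue-usage distribution
  toward a class-specific residue subset;
* a sequence-order channel: a lag-p "echo" (period p, class-specific).
  With coupling probability beta the residue at position i repeats the
  residue at position i - p; otherwise it is a fresh draw from the usage
  distribution.  Copying a draw from the usage distribution preserves the
  marginal composition exactly, so the echo carries no composition
  information; the property autocorrelation it induces lives at lags that
  are multiples of p and at no smaller lag.  Order information is therefore
  invisible to composition alone and to any lambda < p.

Per position the generating distribution mixes the realized residue (weight
rho) with the class usage background, mimicking a profile built around the
query; the matching synthetic PSSM row holds integer log-odds
round(alpha * centered-log-probabilities + noise) clipped to [-10, 10], so
its softmax concentrates on that distribution, with noise inversely scaled
by the signal strength.  Every row has the same shape regardless of echo
status, so profile sharpness itself carries no class information.
signal_strength = 0 makes all classes exchangeable (uniform usage, zero echo
coupling, noisy query-profile PSSMs).  Everything is a deterministic
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import LabeledDataset, write_labels_tsv
from .profiles import (
    ProteinRecord,
    PSSMMatrix,
    standardize_pssm,
    write_ascii_pssm,
    write_fasta,
)
from .properties import RESIDUE_ORDER

#: Default 3-class labels, matching the submitochondrial compartments.
DEFAULT_CLASS_LABELS = ("inner_membrane", "matrix", "outer_membrane")

#: Class-prior ratio of the SML3-983 benchmark (inner : matrix : outer).
SML3_PRIORS = (661, 177, 145)

_ALPHA = 2.0  # log-odds gain: PSSM softmax ~ pi**alpha
_NOISE_SD0 = 2.0  # log-odds noise sd at zero signal
_CLIP = 10  # psiblast-like log-odds range
_RHO = 0.7  # weight of the realized residue in each profile row


class SyntheticSpecError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    Parameters
    ----------
    n_per_class : tuple of int
        Sequences per class (each >= 2); defines the number of classes.
    length_range : (int, int)
        Inclusive sequence-length range; minimum must be >= 3 and should
        exceed the largest lambda the dataset will be used with.
    signal_strength : float
        Nonnegative tilt amplitude; 0 makes classes exchangeable.
    seed : int
        Master seed; output is byte-identical for equal seeds.
    composition_signal, motif_signal : bool
        Enable/disable the two channels independently (both on by default).
    motif_periods : tuple of int or None
        Per-class echo period; 0 selects a diffuse echo (each echo copies a
        uniformly random earlier position), which matches the overall
        dependence level of a periodic class while concentrating at no
        particular lag — the order-free control.  None selects periods
        2, 3, 4, ...
    class_labels : tuple of str or None
        None selects the compartment names for 3 classes, else class0..N.
    """

    n_per_class: tuple[int, ...] = (20, 20, 20)
    length_range: tuple[int, int] = (30, 60)
    signal_strength: float = 4.0
    seed: int = 0
    composition_signal: bool = True
    motif_signal: bool = True
    motif_periods: tuple[int, ...] | None = None
    class_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        npc = tuple(int(n) for n in self.n_per_class)
        if not npc or any(n < 2 for n in npc):
            raise SyntheticSpecError("n_per_class must be >= 2 for every class")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise SyntheticSpecError(
                f"length_range must satisfy 3 <= min <= max, got {self.length_range}"
            )
        if self.signal_strength < 0:
            raise SyntheticSpecError("signal_strength must be nonnegative")
        object.__setattr__(self, "n_per_class", npc)
        object.__setattr__(self, "length_range", (int(lo), int(hi)))
        if self.motif_periods is not None:
            mp = tuple(int(p) for p in self.motif_periods)
            if len(mp) != len(npc) or any(p < 0 for p in mp):
                raise SyntheticSpecError(
                    "motif_periods needs one nonnegative period per class"
                )
            object.__setattr__(self, "motif_periods", mp)
        if self.class_labels is not None:
            cl = tuple(self.class_labels)
            if len(cl) != len(npc) or len(set(cl)) != len(cl):
                raise SyntheticSpecError("class_labels must be unique, one per class")
            object.__setattr__(self, "class_labels", cl)

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)

    def resolved_labels(self) -> tuple[str, ...]:
        if self.class_labels is not None:
            return self.class_labels
        if self.n_classes == 3:
            return DEFAULT_CLASS_LABELS
        return tuple(f"class{c}" for c in range(self.n_classes))

    def resolved_periods(self) -> tuple[int, ...]:
        if self.motif_periods is not None:
            return self.motif_periods
        return tuple(c + 2 for c in range(self.n_classes))


def sml3_spec(n_total: int = 60, **kwargs) -> SyntheticSpec:
    """A 3-class spec with per-class counts proportional to the SML3-983
    benchmark priors (661 : 177 : 145), at desk scale."""
    total = sum(SML3_PRIORS)
    counts = [max(2, round(n_total * p / total)) for p in SML3_PRIORS]
    return SyntheticSpec(n_per_class=tuple(counts), **kwargs)


def easy_spec(seed: int = 0) -> SyntheticSpec:
    """The documented "easy" preset: 3 balanced classes of 20, high signal."""
    return SyntheticSpec(
        n_per_class=(20, 20, 20),
        length_range=(30, 60),
        signal_strength=4.0,
        seed=seed,
    )


def null_spec(seed: int = 0) -> SyntheticSpec:
    """Zero-signal control: classes are exchangeable by construction."""
    return SyntheticSpec(
        n_per_class=(20, 20, 20),
        length_range=(30, 60),
        signal_strength=0.0,
        seed=seed,
    )


def preset_model_config():
    """SVM operating point for the synthetic presets (gamma=8, C=8).

    Synthetic descriptors live on a different scale than real-PSSM
    descriptors, so the presets carry their own kernel width; see the
    methods note for the choice.
    """
    from .classifier import ModelConfig

    return ModelConfig(gamma=8.0, C=8.0)


def _class_tilts(n_classes: int) -> np.ndarray:
    """Class-preference indicators: residue j belongs to class j mod n."""
    tilt = np.zeros((n_classes, 20))
    for j in range(20):
        tilt[j % n_classes, j] = 1.0
    return tilt - tilt.mean(axis=1, keepdims=True)


def _echo_coupling(signal_strength: float) -> float:
    """Echo copy probability beta, saturating at 0.8 for strong signal."""
    return 0.8 * (1.0 - np.exp(-0.5 * signal_strength))


def generate_dataset(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> LabeledDataset:
    """Sample a labeled dataset (records, labels, profiles) from the spec.

    When ``out_dir`` is given, also writes ``sequences.fasta``,
    ``labels.tsv`` and one ``<identifier>.pssm`` file per sequence in the
    psiblast ASCII dialect; the files round-trip losslessly through the
    package's own parsers.
    """
    rng = np.random.default_rng(spec.seed)
    labels_by_class = spec.resolved_labels()
    periods = spec.resolved_periods()
    comp_amp = 0.5 * spec.signal_strength if spec.composition_signal else 0.0
    beta = _echo_coupling(spec.signal_strength) if spec.motif_signal else 0.0
    noise_sd = _NOISE_SD0 / (1.0 + spec.signal_strength)
    tilts = _class_tilts(spec.n_classes)

    records: list[ProteinRecord] = []
    labels: list[str] = []
    pssms: list[PSSMMatrix] = []
    lo, hi = spec.length_range
    for c in range(spec.n_classes):
        logits = comp_amp * tilts[c]
        usage = np.exp(logits - logits.max())
        usage /= usage.sum()
        p = periods[c]
        for i in range(spec.n_per_class[c]):
            ident = f"syn{c}_{i:03d}"
            L = int(rng.integers(lo, hi + 1))
            fresh = rng.choice(20, size=L, p=usage)
            is_echo = rng.random(L) < beta
            idx = np.empty(L, dtype=np.int64)
            start = p if p > 0 else 1
            for pos in range(L):
                if pos >= start and is_echo[pos]:
                    src = pos - p if p > 0 else int(rng.integers(0, pos))
                    idx[pos] = idx[src]
                else:
                    is_echo[pos] = False
                    idx[pos] = fresh[pos]
            seq = "".join(RESIDUE_ORDER[j] for j in idx)
            # generating distribution per position: concentrated on the
            # realized residue, mixed with the class usage background — the
            # same row shape everywhere, as in a real profile of the query
            pi = (1.0 - _RHO) * np.tile(usage, (L, 1))
            pi[np.arange(L), idx] += _RHO
            # integer log-odds concentrating on pi, noise shrinks with signal
            logpi = np.log(pi)
            centered = logpi - logpi.mean(axis=1, keepdims=True)
            E = np.clip(
                np.round(_ALPHA * centered + rng.normal(0.0, noise_sd, (L, 20))),
                -_CLIP,
                _CLIP,
            ).astype(np.int64)
            records.append(ProteinRecord(ident, seq))
            labels.append(labels_by_class[c])
            pssms.append(PSSMMatrix(ident, E, seq))

    profiles = [standardize_pssm(p) for p in pssms]
    dataset = LabeledDataset(records, labels, profiles)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "sequences.fasta")
        write_labels_tsv(dataset, out_dir / "labels.tsv")
        for pssm in pssms:
            write_ascii_pssm(pssm, out_dir / f"{pssm.identifier}.pssm")
    return dataset
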