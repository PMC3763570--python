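"""Descriptor computation: PSPCP values, composition, pseudofactors, and the
final normalized 20 + lambda*R feature vector.

Given a row-stochastic profile A (L x 20) and R z-normalized property scales
h (R x 20), the positional specific physicochemical property (PSPCP) of
position i under property r is the expectation

    d(i, r) = sum_j A(i->j) h(r, j),

i.e. the average property value of position i over its evolutionary
substitution distribution.  The descriptor vector combines

* composition: f(j) = (1/L) sum_i A(i->j), the profile-weighted amino-acid
  composition (20 values, summing to 1);
* pseudofactors: u(k, r) = (1/(L-k)) sum_{i<=L-k} d(i, r) d(i+k, r), the
  lag-k autocorrelation of the PSPCP series for property r, for tiers
  k = 1..lambda — the sequence-order channel;

into q = [f, w*u] / (sum f + w sum u), a vector of length 20 + lambda*R that
sums to 1.  The pseudo block is laid out property-major, tier-minor: entry
20 + (r-1)*lambda + k holds w*u(k, r) (1-based).

With one-hot profiles (no PSSM) d(i, r) collapses to the residue's own
normalized property value and the whole construction degrades to the
amphiphilic pseudo-amino-acid composition (AmPseAAC) of the raw sequence.

Note: u(k, r) is a raw product of signed z-score mixtures and may be
negative, so individual q entries can be negative; only the sum-to-1
property is guaranteed.  ``check_descriptor`` optionally enforces
nonnegativity as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .profiles import (
    ProteinRecord,
    StandardizedProfile,
    load_profile,
    one_hot_profile,
)
from .properties import (
    RESIDUE_ORDER,
    NormalizedPropertyTable,
    default_property_table,
)

logger = logging.getLogger(__name__)


class FeatureError(ValueError):
    """Raised for invalid feature configurations or pathological inputs."""


@dataclass(frozen=True)
class FeatureConfig:
    """Descriptor parameters.

    Parameters
    ----------
    w : float
        Weight of the sequence-order (pseudofactor) block, in (0, 1).
    lam : int
        Number of autocorrelation tiers lambda (>= 1); must be smaller than
        every sequence length it is applied to.
    property_accessions : tuple of str
        Ordered accessions of the property scales used; defines R.
    """

    w: float = 0.15
    lam: int = 11
    property_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.w < 1.0):
            raise FeatureError(f"w must be in (0, 1), got {self.w}")
        if int(self.lam) != self.lam or self.lam < 1:
            raise FeatureError(f"lambda must be a positive integer, got {self.lam}")
        object.__setattr__(self, "lam", int(self.lam))
        object.__setattr__(
            self, "property_accessions", tuple(self.property_accessions)
        )

    @property
    def R(self) -> int:
        return len(self.property_accessions)

    @property
    def n_features(self) -> int:
        return 20 + self.lam * self.R


@dataclass(frozen=True)
class DescriptorVector:
    """The 20 + lambda*R descriptors of one protein."""

    identifier: str
    q: np.ndarray = dc_field(repr=False)
    config: FeatureConfig = dc_field(default=None)  # type: ignore[assignment]


def pspcp(
    profile: StandardizedProfile, props: NormalizedPropertyTable
) -> np.ndarray:
    """PSPCP matrix ``d`` of shape (L, R): d[i, r] = sum_j A[i, j] h[r, j]."""
    return profile.A @ props.h.T


def composition(profile: StandardizedProfile) -> np.ndarray:
    """Profile-weighted amino-acid composition: the 20 column means of A."""
    return profile.A.mean(axis=0)


def pseudofactors(d: np.ndarray, lam: int, identifier: str = "") -> np.ndarray:
    """Lag-k autocorrelation factors u of shape (lam, R).

    u[k-1, r] = (1/(L-k)) sum_{i=1}^{L-k} d[i, r] * d[i+k, r].

    Raises
    ------
    FeatureError
        If ``lam >= L`` (tier k = lam would have no terms).
    """
    L = d.shape[0]
    if lam >= L:
        raise FeatureError(
            f"lambda = {lam} requires sequence length > lambda, but "
            f"{identifier or 'sequence'} has length {L}"
        )
    u = np.empty((lam, d.shape[1]))
    for k in range(1, lam + 1):
        u[k - 1] = (d[:-k] * d[k:]).mean(axis=0)
    return u


def descriptor_vector(
    profile: StandardizedProfile,
    props: NormalizedPropertyTable,
    config: FeatureConfig,
) -> DescriptorVector:
    """The normalized descriptor vector q of length 20 + lambda*R.

    First 20 entries: f(j)/Z.  Entry 20 + (r-1)*lambda + k (1-based):
    w*u(k, r)/Z.  Z = sum_j f(j) + w * sum_{r,k} u(k, r).

    Raises
    ------
    FeatureError
        If lambda >= L, if R mismatches the property table, or if the shared
        denominator Z is non-positive or non-finite.
    """
    if config.R and config.R != props.R:
        raise FeatureError(
            f"config names {config.R} properties but table has {props.R}"
        )
    f = composition(profile)
    d = pspcp(profile, props)
    u = pseudofactors(d, config.lam, identifier=profile.identifier)
    q = assemble_descriptor(f, u, config.w, identifier=profile.identifier)
    return DescriptorVector(profile.identifier, q, config)


def assemble_descriptor(
    f: np.ndarray, u: np.ndarray, w: float, identifier: str = ""
) -> np.ndarray:
    """Combine a composition vector and a pseudofactor matrix with weight w.

    Split out so that calibration can sweep w without recomputing f and u.
    """
    # property-major, tier-minor flattening: all lam tiers of property 1 first
    pseudo = u.ravel(order="F")
    Z = f.sum() + w * pseudo.sum()
    if not np.isfinite(Z) or Z <= 0:
        raise FeatureError(
            f"{identifier or 'sequence'}: pathological profile, shared "
            f"denominator Z = {Z!r} is not a positive finite number"
        )
    return np.concatenate([f, w * pseudo]) / Z


def check_descriptor(
    q: np.ndarray, config: FeatureConfig, require_nonnegative: bool = False
) -> None:
    """Diagnostics: verify length and sum-to-1; optionally nonnegativity.

    Negative entries can legitimately arise from negative pseudofactors, so
    nonnegativity is opt-in rather than an invariant.
    """
    if q.shape != (config.n_features,):
        raise FeatureError(
            f"descriptor length {q.shape} != expected ({config.n_features},)"
        )
    if abs(q.sum() - 1.0) > 1e-9:
        raise FeatureError(f"descriptor sums to {q.sum()!r}, expected 1")
    if require_nonnegative and np.any(q < 0):
        raise FeatureError("descriptor has negative entries")


def feature_names(config: FeatureConfig) -> list[str]:
    """Column names: f_A..f_V, then u_<accession>_k<k>, property-major."""
    names = [f"f_{aa}" for aa in RESIDUE_ORDER]
    accs = config.property_accessions or tuple(
        f"prop{r + 1}" for r in range(config.R)
    )
    for acc in accs:
        names.extend(f"u_{acc}_k{k}" for k in range(1, config.lam + 1))
    return names


class PspcpVectorizer(TransformerMixin, BaseEstimator):
    """Transform standardized profiles into descriptor matrices.

    A scikit-learn transformer: ``fit`` resolves and normalizes the property
    table; ``transform`` maps a list of :class:`StandardizedProfile` (or
    :class:`ProteinRecord`, which one-hot degrade) to an (n, 20 + lambda*R)
    array.

    Parameters
    ----------
    w : float, default 0.15
        Sequence-order weight.
    lam : int, default 11
        Autocorrelation depth lambda.
    properties : NormalizedPropertyTable or None
        Property table; None selects the nine bundled AAindex scales.

    Attributes
    ----------
    property_table_ : NormalizedPropertyTable
    config_ : FeatureConfig
    feature_names_ : list of str
    n_features_out_ : int
    """

    def __init__(self, w: float = 0.15, lam: int = 11, properties=None):
        self.w = w
        self.lam = lam
        self.properties = properties

    def fit(self, X=None, y=None):
        table = self.properties
        if table is None:
            table = default_property_table()
        self.property_table_ = table
        self.config_ = FeatureConfig(
            w=self.w, lam=self.lam, property_accessions=table.source_accessions
        )
        self.feature_names_ = feature_names(self.config_)
        self.n_features_out_ = self.config_.n_features
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit()
        rows = []
        for item in X:
            profile = (
                item
                if isinstance(item, StandardizedProfile)
                else one_hot_profile(item)
            )
            rows.append(
                descriptor_vector(profile, self.property_table_, self.config_).q
            )
        return np.vstack(rows) if rows else np.empty((0, self.n_features_out_))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


@dataclass
class FeatureExtraction:
    """Result of :func:`extract_features`."""

    X: np.ndarray
    identifiers: list[str]
    origins: list[str]
    feature_names: list[str]
    errors: list[tuple[str, str]]  # (identifier, message) for skipped records


def extract_features(
    records: list[ProteinRecord],
    pssm_dir=None,
    props: NormalizedPropertyTable | None = None,
    config: FeatureConfig | None = None,
    strict: bool = False,
) -> FeatureExtraction:
    """Descriptor matrix for a list of records, with per-record PSSM lookup.

    Each record's profile comes from ``<identifier>.pssm`` under ``pssm_dir``
    when present, else the one-hot fallback.  Per-record failures (for
    example a sequence shorter than lambda) abort in strict mode; otherwise
    the record is skipped and reported in ``errors``.
    """
    if not records:
        raise FeatureError("no records to extract features from")
    if props is None:
        props = default_property_table()
    if config is None:
        config = FeatureConfig(property_accessions=props.source_accessions)
    elif not config.property_accessions:
        config = FeatureConfig(
            w=config.w, lam=config.lam, property_accessions=props.source_accessions
        )
    rows, ids, origins, errors = [], [], [], []
    for rec in records:
        try:
            profile = load_profile(rec, pssm_dir)
            vec = descriptor_vector(profile, props, config)
        except Exception as exc:  # noqa: BLE001 - reported per record
            if strict:
                raise FeatureError(f"record {rec.identifier!r}: {exc}") from exc
            errors.append((rec.identifier, str(exc)))
            continue
        rows.append(vec.q)
        ids.append(rec.identifier)
        origins.append(profile.origin)
    if not rows:
        raise FeatureError(
            "all records failed feature extraction: "
            + "; ".join(f"{i}: {m}" for i, m in errors)
        )
    n_fallback = origins.count("one_hot")
    logger.info(
        "extracted %d descriptor vectors (%d one-hot fallbacks, %d skipped)",
        len(rows),
        n_fallback,
        len(errors),
    )
    return FeatureExtraction(
        np.vstack(rows), ids, origins, feature_names(config), errors
    )


def write_feature_tsv(result: FeatureExtraction, path) -> None:
    """Write a feature matrix as TSV: identifier column, named features,
    17 significant digits (lossless float round-trip)."""
    import pandas as pd

    df = pd.DataFrame(result.X, columns=result.feature_names)
    df.insert(0, "identifier", result.identifiers)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_tsv(path):
    """Read a feature TSV back into (X, identifiers, feature_names)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "identifier":
        raise FeatureError("feature TSV must start with an 'identifier' column")
    ids = df["identifier"].astype(str).tolist()
    names = df.columns[1:].tolist()
    return df.iloc[:, 1:].to_numpy(dtype=float), ids, names
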