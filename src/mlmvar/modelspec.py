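"""Declarative specification of multilevel latent moderated VAR models.

A model is described by its latent constructs (each measured by one or
several observed indicators) and by the lagged terms of the within-person
dynamic equations: autoregressive (AR) carryover effects, cross-regressive
(CR) effects of one construct on another, and pairwise latent interaction
(moderation) terms.  The same :class:`ModelSpec` object drives the data
simulator and the Bayesian estimator, so that both operate on exactly the
same structure.

Constructs and indicators are 1-indexed in user-facing labels (``phi_21``
is the effect of construct 1 on construct 2, matching the common eta/phi
notation for these models); internal storage is 0-indexed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable

import yaml

from .errors import ConfigurationError

__all__ = [
    "ConstructDef",
    "LagTerm",
    "ModelSpec",
    "build_model",
    "parameter_index",
    "ParameterIndex",
    "ParamEntry",
]


@dataclass(frozen=True)
class ConstructDef:
    """One latent construct and its measurement structure.

    ``single_indicator=True`` means the observed variable is taken as an
    error-free measure of the construct (no within/between measurement
    parameters).  With multiple indicators, the first loading is fixed to 1
    and the first intercept to 0 for identification; free loadings require
    at least three indicators.
    """

    name: str
    n_indicators: int = 1
    loadings_free: bool = False

    @property
    def single_indicator(self) -> bool:
        return self.n_indicators == 1

    def validate(self) -> None:
        if self.n_indicators < 1:
            raise ConfigurationError(
                f"construct {self.name!r}: n_indicators must be positive"
            )
        if self.loadings_free and self.n_indicators < 3:
            raise ConfigurationError(
                f"construct {self.name!r}: free loadings require >= 3 indicators "
                "for identification"
            )


@dataclass(frozen=True)
class LagTerm:
    """One term of a within-person dynamic equation.

    ``outcome`` and ``predictor`` are 0-based construct indices.  For
    interaction terms the regressor is the product of two (possibly
    differently lagged) within-level latent states, ``predictor`` at
    ``lag`` times ``second_predictor`` at ``second_lag``.  ``lag = 0`` is
    allowed only for CR/interaction predictors entering at the same
    measurement occasion; the resulting same-time dependency graph must be
    acyclic.
    """

    outcome: int
    predictor: int
    kind: str = "AR"  # AR | CR | interaction
    lag: int = 1
    second_predictor: int | None = None
    second_lag: int = 1
    random: bool = False

    @property
    def label(self) -> str:
        k, q = self.outcome + 1, self.predictor + 1
        if self.kind == "interaction":
            return f"phi_{k}.{q}{self.second_predictor + 1}"
        return f"phi_{k}{q}"

    def validate(self, n_constructs: int) -> None:
        if self.kind not in ("AR", "CR", "interaction"):
            raise ConfigurationError(f"unknown term kind {self.kind!r}")
        for idx in (self.outcome, self.predictor):
            if not 0 <= idx < n_constructs:
                raise ConfigurationError(f"construct index {idx} out of range")
        if self.lag not in (0, 1) or self.second_lag not in (0, 1):
            raise ConfigurationError("only lags 0 and 1 are supported")
        if self.kind == "AR":
            if self.outcome != self.predictor or self.lag != 1:
                raise ConfigurationError(
                    "AR terms must have outcome == predictor and lag == 1"
                )
            if self.second_predictor is not None:
                raise ConfigurationError("AR terms take a single predictor")
        if self.kind == "CR" and self.second_predictor is not None:
            raise ConfigurationError("CR terms take a single predictor")
        if self.kind == "interaction":
            if self.second_predictor is None:
                raise ConfigurationError("interaction terms need second_predictor")
            if not 0 <= self.second_predictor < n_constructs:
                raise ConfigurationError("second_predictor out of range")


@dataclass
class ModelSpec:
    """Full declarative model description.

    ``innovation_covariance`` is one of ``"none"`` (independent
    innovations), ``"fixed"`` (one covariance shared by all persons) or
    ``"random"`` (person-specific, via the common-factor construction with
    log-normally distributed components).  Latent person means are always
    person-specific (random), as in all model variants considered here.
    """

    constructs: list[ConstructDef]
    terms: list[LagTerm]
    innovation_covariance: str = "none"
    random_innovation_variances: bool = False
    between_errors: bool = False
    innovation_covariance_sign: int = 1
    name: str = "custom"

    # -- structure queries -------------------------------------------------
    @property
    def n_constructs(self) -> int:
        return len(self.constructs)

    @property
    def any_factor(self) -> bool:
        return any(not c.single_indicator for c in self.constructs)

    @property
    def has_random_phi(self) -> bool:
        return any(t.random for t in self.terms)

    def terms_for_outcome(self, k: int) -> list[LagTerm]:
        return [t for t in self.terms if t.outcome == k]

    def lag0_graph(self) -> dict[int, set[int]]:
        """Edges predictor -> outcome among same-occasion dependencies."""
        edges: dict[int, set[int]] = {q: set() for q in range(self.n_constructs)}
        for t in self.terms:
            if t.lag == 0:
                edges[t.predictor].add(t.outcome)
            if t.kind == "interaction" and t.second_lag == 0:
                edges[t.second_predictor].add(t.outcome)
        return edges

    def lag0_order(self) -> list[int]:
        """Topological order of constructs w.r.t. same-occasion terms.

        Raises ConfigurationError when the lag-0 graph has a cycle.
        """
        edges = self.lag0_graph()
        indeg = {q: 0 for q in range(self.n_constructs)}
        for src, dsts in edges.items():
            for d in dsts:
                indeg[d] += 1
        queue = sorted(q for q, d in indeg.items() if d == 0)
        order: list[int] = []
        while queue:
            q = queue.pop(0)
            order.append(q)
            for d in sorted(edges[q]):
                indeg[d] -= 1
                if indeg[d] == 0:
                    queue.append(d)
        if len(order) != self.n_constructs:
            raise ConfigurationError("same-occasion (lag-0) dependencies are cyclic")
        return order

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if not self.constructs:
            raise ConfigurationError("a model needs at least one construct")
        if self.n_constructs > 3:
            raise ConfigurationError("at most 3 constructs are supported")
        names = [c.name for c in self.constructs]
        if len(set(names)) != len(names):
            raise ConfigurationError("construct names must be unique")
        for c in self.constructs:
            c.validate()
        if not self.terms:
            raise ConfigurationError("a model needs at least one dynamic term")
        for t in self.terms:
            t.validate(self.n_constructs)
        if len({(t.outcome, t.predictor, t.kind, t.lag, t.second_predictor, t.second_lag) for t in self.terms}) != len(self.terms):
            raise ConfigurationError("duplicate dynamic terms")
        if self.innovation_covariance not in ("none", "fixed", "random"):
            raise ConfigurationError(
                f"unknown innovation_covariance {self.innovation_covariance!r}"
            )
        if self.innovation_covariance == "random" and not self.random_innovation_variances:
            raise ConfigurationError(
                "random innovation covariance requires random innovation variances "
                "(the common-factor construction couples them)"
            )
        if self.innovation_covariance_sign not in (-1, 1):
            raise ConfigurationError("innovation_covariance_sign must be +1 or -1")
        # every construct used as a predictor needs its own dynamic equation
        predictors = set()
        for t in self.terms:
            predictors.add(t.predictor)
            if t.second_predictor is not None:
                predictors.add(t.second_predictor)
        for q in predictors:
            if not any(t.outcome == q and t.kind == "AR" for t in self.terms):
                raise ConfigurationError(
                    f"construct {self.constructs[q].name!r} is used as a predictor "
                    "but has no AR(1) equation of its own"
                )
        self.lag0_order()  # raises on cyclic same-occasion structure

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for t in d["terms"]:
            if t["second_predictor"] is None:
                del t["second_predictor"], t["second_lag"]
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        constructs = [ConstructDef(**c) for c in d["constructs"]]
        terms = [LagTerm(**t) for t in d["terms"]]
        keys = (
            "innovation_covariance",
            "random_innovation_variances",
            "between_errors",
            "innovation_covariance_sign",
            "name",
        )
        kwargs = {k: d[k] for k in keys if k in d}
        spec = cls(constructs=constructs, terms=terms, **kwargs)
        spec.validate()
        return spec

    @classmethod
    def from_yaml(cls, text_or_path: str) -> "ModelSpec":
        try:
            with open(text_or_path) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = text_or_path
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Builders for the canonical model variants
# ---------------------------------------------------------------------------

def _constructs(names: Iterable[str], factor: bool) -> list[ConstructDef]:
    if factor:
        return [ConstructDef(n, n_indicators=3, loadings_free=True) for n in names]
    return [ConstructDef(n) for n in names]


def build_model(
    name: str,
    random_effects: bool = False,
    factor: bool = False,
    inncov: bool = False,
) -> ModelSpec:
    """Construct one of the canonical model variants.

    ``name`` is one of ``"A"``, ``"B"``, ``"C"`` or ``"ex2"``:

    * **A** -- two constructs; construct 1 follows an AR(1) process and
      predicts construct 2, whose AR effect is moderated by the lagged
      product of both states.
    * **B** -- Model A with a fully crossed lagged structure: both
      constructs receive CR and interaction terms.
    * **C** -- three constructs; construct 1 (AR(1) only) moderates the
      fully crossed dynamics between constructs 2 and 3.
    * **ex2** -- two constructs with a same-occasion (lag-0) effect of
      construct 1 on construct 2 and a lag-0 x lag-1 interaction, the
      structure used for reciprocal rumination/negative-affect dynamics.
      Defaults to a random-effects single-indicator model.

    Flags: ``random_effects`` makes all phi terms and the innovation
    (co)variances person-specific; ``factor`` uses three indicators per
    construct with free loadings; ``inncov`` adds an innovation covariance
    (fixed across persons in fixed-effects models, person-specific via the
    common-factor construction in random-effects models).
    """
    r = bool(random_effects)
    if name == "A":
        terms = [
            LagTerm(0, 0, "AR", random=r),
            LagTerm(1, 0, "CR", random=r),
            LagTerm(1, 1, "AR", random=r),
            LagTerm(1, 0, "interaction", second_predictor=1, random=r),
        ]
        cons = _constructs(["eta1", "eta2"], factor)
    elif name == "B":
        terms = [
            LagTerm(0, 0, "AR", random=r),
            LagTerm(0, 1, "CR", random=r),
            LagTerm(0, 0, "interaction", second_predictor=1, random=r),
            LagTerm(1, 0, "CR", random=r),
            LagTerm(1, 1, "AR", random=r),
            LagTerm(1, 0, "interaction", second_predictor=1, random=r),
        ]
        cons = _constructs(["eta1", "eta2"], factor)
    elif name == "C":
        terms = [
            LagTerm(0, 0, "AR", random=r),
            LagTerm(1, 0, "CR", random=r),
            LagTerm(1, 1, "AR", random=r),
            LagTerm(1, 2, "CR", random=r),
            LagTerm(1, 0, "interaction", second_predictor=2, random=r),
            LagTerm(1, 0, "interaction", second_predictor=1, random=r),
            LagTerm(2, 0, "CR", random=r),
            LagTerm(2, 1, "CR", random=r),
            LagTerm(2, 2, "AR", random=r),
            LagTerm(2, 0, "interaction", second_predictor=2, random=r),
            LagTerm(2, 0, "interaction", second_predictor=1, random=r),
        ]
        cons = _constructs(["eta1", "eta2", "eta3"], factor)
    elif name == "ex2":
        r = True  # the canonical use of this variant is fully random-effects
        # reciprocal dynamics with a same-occasion predictor: construct 1
        # (e.g., rumination over the elapsed interval) enters the equation
        # of construct 2 (e.g., current negative affect) at lag 0.
        terms = [
            LagTerm(0, 0, "AR", random=r),
            LagTerm(0, 1, "CR", random=r),
            LagTerm(1, 0, "CR", lag=0, random=r),
            LagTerm(1, 1, "AR", random=r),
            LagTerm(1, 0, "interaction", lag=0, second_predictor=1, second_lag=1, random=r),
        ]
        cons = _constructs(["eta1", "eta2"], factor)
    else:
        raise ConfigurationError(f"unknown model name {name!r}")

    spec = ModelSpec(
        constructs=cons,
        terms=terms,
        innovation_covariance=("random" if (inncov and r) else "fixed" if inncov else "none"),
        random_innovation_variances=r,
        name=name,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Parameter index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamEntry:
    """One named free parameter on the reporting (constrained) scale.

    ``transform`` names the map from the sampler's unconstrained axis to
    the reporting scale: identity, ``log`` (positive scales) or ``corr``
    (entries jointly produced from a Cholesky-correlation transform of the
    group's unconstrained vector).
    """

    name: str
    category: str
    transform: str = "identity"
    group: str | None = None


@dataclass
class ParameterIndex:
    """Stable ordering of all free parameters of a model.

    The estimator's draw matrix has one column per entry, in this order.
    ``person_effects`` lists the person-varying quantities that make up the
    between-level multivariate normal (traits first, then random phi
    coefficients, then log innovation-variance components).
    """

    entries: list[ParamEntry]
    person_effects: list[str]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def size(self) -> int:
        return len(self.entries)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def by_category(self, category: str) -> list[str]:
        return [e.name for e in self.entries if e.category == category]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "category": [e.category for e in self.entries],
                "transform": [e.transform for e in self.entries],
                "group": [e.group for e in self.entries],
            }
        )


def _corr_pair_names(labels: list[str]) -> list[str]:
    out = []
    for i in range(1, len(labels)):
        for j in range(i):
            out.append(f"rho({labels[j]},{labels[i]})")
    return out


def person_effect_names(spec: ModelSpec) -> list[str]:
    names = [f"mu_{q + 1}" for q in range(spec.n_constructs)]
    names += [t.label for t in spec.terms if t.random]
    if spec.random_innovation_variances:
        names += [f"ln_sigma2_delta_{q + 1}" for q in range(spec.n_constructs)]
        if spec.innovation_covariance == "random":
            names.append("ln_sigma2_etazeta")
    return names


def parameter_index(spec: ModelSpec) -> ParameterIndex:
    """Enumerate all free parameters of ``spec`` in a stable, documented order.

    Order: dynamic fixed effects; innovation scale/correlation parameters;
    trait means; random-effect scales (traits, then random phi terms, then
    log innovation variances); between-level random-effect correlations;
    measurement parameters (within loadings, intercepts, within error SDs,
    between loadings, optional between error SDs), construct by construct.
    """
    spec.validate()
    entries: list[ParamEntry] = []
    Q = spec.n_constructs

    for t in spec.terms:
        entries.append(ParamEntry(t.label, "phi"))

    if spec.random_innovation_variances:
        for q in range(Q):
            entries.append(ParamEntry(f"gamma_ln_sigma2_delta_{q + 1}", "innovation"))
        if spec.innovation_covariance == "random":
            entries.append(ParamEntry("gamma_ln_sigma2_etazeta", "innovation"))
    else:
        for q in range(Q):
            entries.append(ParamEntry(f"sigma_zeta_{q + 1}", "innovation", "log"))
        if spec.innovation_covariance == "fixed":
            labels = [f"zeta_{q + 1}" for q in range(Q)]
            for nm in _corr_pair_names(labels):
                entries.append(ParamEntry(nm, "innovation", "corr", group="inncorr"))

    for q in range(Q):
        entries.append(ParamEntry(f"gamma_mu_{q + 1}", "trait"))

    eff = person_effect_names(spec)
    for nm in eff:
        entries.append(ParamEntry(f"tau_{nm}", "re_scale", "log"))
    if len(eff) > 1:
        for nm in _corr_pair_names(eff):
            entries.append(ParamEntry(nm, "re_corr", "corr", group="recorr"))

    for q, c in enumerate(spec.constructs):
        if c.single_indicator:
            continue
        P = c.n_indicators
        if c.loadings_free:
            for p in range(1, P):
                entries.append(ParamEntry(f"lambda_w_{q + 1}_{p + 1}", "measurement"))
        for p in range(1, P):
            entries.append(ParamEntry(f"alpha_{q + 1}_{p + 1}", "measurement"))
        for p in range(P):
            entries.append(ParamEntry(f"sigma_eps_w_{q + 1}_{p + 1}", "measurement", "log"))
        if c.loadings_free:
            for p in range(1, P):
                entries.append(ParamEntry(f"lambda_b_{q + 1}_{p + 1}", "measurement"))
        if spec.between_errors:
            for p in range(P):
                entries.append(ParamEntry(f"sigma_eps_b_{q + 1}_{p + 1}", "measurement", "log"))

    return ParameterIndex(entries=entries, person_effects=eff)
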