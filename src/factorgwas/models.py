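"""Confirmatory factor model specifications for genomic covariance matrices.

A :class:`ModelSpec` declares factors, a loading pattern (free or fixed
values), factor variances/covariances, residual variances and correlated
residual pairs.  Identification is by unit factor variance (standardized
solutions); factor covariances default to fixed zero (orthogonal) unless
declared.  Specs can be written programmatically or in a compact
lavaan-style text DSL::

    EF =~ trail + pairs + digit
    WM =~ digit + pairs
    WM ~~ EF            # free factor covariance
    pairs ~~ digit      # free correlated residual
    trail ~~ 0*trail    # residual variance fixed to 0

``model_zoo`` returns the nine competing structures for the executive
function indicator panel: a common-factor model, correlated three-factor
(unity-diversity) models with and without an orthogonal substitution
task factor, and bifactor variants with a general EF factor plus
orthogonal working-memory and substitution factors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["ModelSpec", "count_free_params", "model_zoo", "parse_model_dsl",
           "EF_INDICATORS", "endorsed_model", "endorsed_model_literal"]

FREE = None  # sentinel: parameter is free


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ModelSpec:
    """A genomic CFA structure over a fixed set of indicators."""

    name: str
    indicators: list[str]
    factors: list[str]
    #: (indicator, factor) -> None (free) or fixed value; absent = no loading
    loadings: dict[tuple[str, str], float | None]
    #: unordered factor pair -> None (free) or fixed value; absent = fixed 0
    factor_covs: dict[tuple[str, str], float | None] = field(default_factory=dict)
    #: factor -> None (free) or fixed value; absent = fixed 1 (identification)
    factor_vars: dict[str, float | None] = field(default_factory=dict)
    #: indicator -> None (free, default) or fixed value
    residuals: dict[str, float | None] = field(default_factory=dict)
    #: unordered indicator pair -> None (free) or fixed value
    residual_covs: dict[tuple[str, str], float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind in self.indicators:
            self.residuals.setdefault(ind, FREE)
        loaded = {i for (i, _f) in self.loadings}
        missing = [i for i in self.indicators if i not in loaded]
        if self.factors and missing:
            raise ValueError(f"{self.name}: indicators load on no factor: {missing}")
        for (i, f) in self.loadings:
            if i not in self.indicators or f not in self.factors:
                raise ValueError(f"{self.name}: unknown loading pair ({i}, {f})")

    def free_parameters(self) -> list[tuple[str, object]]:
        """Ordered list of (kind, key) for every free parameter."""
        out: list[tuple[str, object]] = []
        out += [("loading", k) for k, v in self.loadings.items() if v is FREE]
        out += [("factor_cov", k) for k, v in self.factor_covs.items() if v is FREE]
        out += [("factor_var", k) for k, v in self.factor_vars.items() if v is FREE]
        out += [("residual", k) for k, v in self.residuals.items() if v is FREE]
        out += [("residual_cov", k) for k, v in self.residual_covs.items() if v is FREE]
        return out

    def n_free(self) -> int:
        return len(self.free_parameters())

    def n_moments(self) -> int:
        t = len(self.indicators)
        return t * (t + 1) // 2

    def degrees_of_freedom(self) -> int:
        return self.n_moments() - self.n_free()

    def reorder(self, indicators: list[str]) -> "ModelSpec":
        if set(indicators) != set(self.indicators):
            raise ValueError("reorder must preserve the indicator set")
        return ModelSpec(self.name, list(indicators), list(self.factors),
                         dict(self.loadings), dict(self.factor_covs),
                         dict(self.factor_vars), dict(self.residuals),
                         dict(self.residual_covs))


def count_free_params(spec: ModelSpec) -> int:
    """Free loadings + residual (co)variances + factor (co)variances."""
    return spec.n_free()


# --- text DSL -----------------------------------------------------------

_FIXED_RE = re.compile(r"^([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)\*(.+)$")


def _parse_term(tok: str) -> tuple[str, float | None]:
    tok = tok.strip()
    m = _FIXED_RE.match(tok)
    if m:
        return m.group(2).strip(), float(m.group(1))
    return tok, FREE


def parse_model_dsl(text: str, name: str = "custom") -> ModelSpec:
    """Parse the compact text DSL into a :class:`ModelSpec`."""
    loadings: dict[tuple[str, str], float | None] = {}
    factors: list[str] = []
    indicators: list[str] = []
    cov_lines: list[tuple[str, str, float | None]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=~" in line:
            lhs, rhs = line.split("=~", 1)
            fac = lhs.strip()
            if fac not in factors:
                factors.append(fac)
            for tok in rhs.split("+"):
                ind, val = _parse_term(tok)
                loadings[(ind, fac)] = val
                if ind not in indicators:
                    indicators.append(ind)
        elif "~~" in line:
            lhs, rhs = line.split("~~", 1)
            a = lhs.strip()
            b, val = _parse_term(rhs)
            cov_lines.append((a, b, val))
        else:
            raise ValueError(f"cannot parse model line: {raw!r}")
    spec = ModelSpec(name, indicators, factors, loadings)
    for a, b, val in cov_lines:
        if a in factors and b in factors:
            if a == b:
                spec.factor_vars[a] = val
            else:
                spec.factor_covs[_pair(a, b)] = val
        elif a in indicators and b in indicators:
            if a == b:
                spec.residuals[a] = val
            else:
                spec.residual_covs[_pair(a, b)] = val
        else:
            raise ValueError(f"unknown variables in covariance line: {a} ~~ {b}")
    return spec


# --- the executive-function model zoo -----------------------------------

#: the nine retained indicators, in panel order
EF_INDICATORS = [
    "UKB_Trails", "UKB_Pairs", "UKB_SDST", "UKB_Digit", "UKB_PMemory",
    "CHARGE_DSST", "CHARGE_Stroop", "ALSPAC_WM", "NIH_G4",
]

_WM = ["UKB_Digit", "UKB_Pairs", "ALSPAC_WM", "NIH_G4"]
_SUB = ["UKB_SDST", "CHARGE_DSST"]
_SHIFT = ["UKB_Trails", "UKB_SDST", "CHARGE_DSST"]
_INH = ["UKB_PMemory", "CHARGE_Stroop"]
_PM_RESID = _pair("UKB_PMemory", "ALSPAC_WM")


def _spec(name, factors, loadings, *, covs=(), resid_fix=(), resid_covs=()):
    spec = ModelSpec(name, list(EF_INDICATORS), list(factors),
                     {k: FREE for k in loadings})
    for pair in covs:
        spec.factor_covs[_pair(*pair)] = FREE
    for ind, val in resid_fix:
        spec.residuals[ind] = val
    for pair in resid_covs:
        spec.residual_covs[_pair(*pair)] = FREE
    return spec


def _load(factor, inds):
    return [(i, factor) for i in inds]


def endorsed_model() -> ModelSpec:
    """Bifactor with orthogonal working-memory and substitution factors.

    A general EF factor loads all nine indicators; working memory loads
    the digit span, pairs matching, ALSPAC working memory and NIH G4
    indicators; substitution loads the two symbol/digit substitution
    tasks; the prospective memory / ALSPAC pair keeps a correlated
    residual.  All factors mutually orthogonal.

    A two-indicator orthogonal specific factor with both residual
    variances free leaves one flat direction (only the loading product
    is identified), so, as in the three-factor substitution variant, the
    CHARGE DSST residual variance is fixed to 0 for identification;
    24 free parameters.  :func:`endorsed_model_literal` keeps the
    residual free and is empirically under-identified.
    """
    return _spec(
        "bifactor_wm_substitution", ["EF", "WM", "SUB"],
        _load("EF", EF_INDICATORS) + _load("WM", _WM) + _load("SUB", _SUB),
        resid_fix=[("CHARGE_DSST", 0.0)],
        resid_covs=[_PM_RESID],
    )


def endorsed_model_literal() -> ModelSpec:
    """The endorsed structure with the CHARGE DSST residual left free.

    25 free parameters, of which only 24 are empirically identified:
    the substitution loadings and the two substitution-task residuals
    trade off along a flat manifold, so fitting this spec reports a
    singular information matrix.  Kept for documentation and tests.
    """
    spec = endorsed_model()
    spec.name = "bifactor_wm_substitution_literal"
    spec.residuals["CHARGE_DSST"] = FREE
    return spec


def model_zoo() -> dict[str, ModelSpec]:
    """The nine competing structures fitted to the nine-indicator panel."""
    zoo: dict[str, ModelSpec] = {}

    zoo["common_factor"] = _spec(
        "common_factor", ["EF"], _load("EF", EF_INDICATORS))

    zoo["three_factor"] = _spec(
        "three_factor", ["SHIFT", "WM", "INH"],
        _load("SHIFT", _SHIFT) + _load("WM", _WM) + _load("INH", _INH),
        covs=[("SHIFT", "WM"), ("SHIFT", "INH"), ("WM", "INH")],
        resid_covs=[_PM_RESID],
    )

    zoo["three_factor_substitution"] = _spec(
        "three_factor_substitution", ["SHIFT", "WM", "INH", "SUB"],
        _load("SHIFT", _SHIFT) + _load("WM", _WM) + _load("INH", _INH)
        + _load("SUB", _SUB),
        covs=[("SHIFT", "WM"), ("SHIFT", "INH"), ("WM", "INH")],
        resid_fix=[("CHARGE_DSST", 0.0)],  # avoids empirical under-identification
        resid_covs=[_PM_RESID],
    )

    zoo["bifactor_wm"] = _spec(
        "bifactor_wm", ["EF", "WM"],
        _load("EF", EF_INDICATORS) + _load("WM", _WM),
        resid_covs=[_PM_RESID],
    )

    zoo["bifactor_wm_substitution"] = endorsed_model()

    sub_shift = _spec(
        "bifactor_wm_substitution_shifting", ["EF", "WM", "SUB"],
        _load("EF", EF_INDICATORS) + _load("WM", _WM)
        + _load("SUB", _SUB + ["UKB_Trails"]),
        resid_covs=[_PM_RESID],
    )
    zoo["bifactor_wm_substitution_shifting"] = sub_shift

    drop_pairs = endorsed_model()
    drop_pairs.name = "bifactor_drop_pairs_wm"
    del drop_pairs.loadings[("UKB_Pairs", "WM")]
    zoo["bifactor_drop_pairs_wm"] = drop_pairs

    prospective = _spec(
        "bifactor_prospective_wm", ["EF", "WM", "SUB"],
        _load("EF", EF_INDICATORS) + _load("WM", _WM + ["UKB_PMemory"])
        + _load("SUB", _SUB),
        resid_fix=[("CHARGE_DSST", 0.0)],  # two-indicator factor identification
    )
    zoo["bifactor_prospective_wm"] = prospective

    zoo["bifactor_wm_substitution_residual"] = _spec(
        "bifactor_wm_substitution_residual", ["EF", "WM"],
        _load("EF", EF_INDICATORS) + _load("WM", _WM),
        resid_covs=[_PM_RESID, _pair(*_SUB)],
    )
    return zoo
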