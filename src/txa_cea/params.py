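"""Model parameterisation: loading, validation and serialisation.

The full model input set — treatment effect, 28-day mortality, excess-mortality
ratios, utilities, unit costs, per-arm trial resource use and run settings — is
held in a single :class:`ParameterSet` built from a YAML configuration file.
A complete default configuration is shipped with the package
(``txa_cea/data/default_config.yaml``).

Event counts (e.g. 548/5981 deaths) are stored as numerator/denominator pairs
rather than proportions so that probabilistic sampling can use the exact
counts.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

ARMS = ("txa", "no_txa")
PROCEDURE_TYPES = (
    "endoscopy_diagnostic",
    "endoscopy_therapeutic",
    "surgery",
    "radiology_diagnostic",
    "radiology_therapeutic",
)
TRANSFUSION_TYPES = ("blood", "ffp", "platelets")


class ConfigError(ValueError):
    """Raised when a configuration file cannot be parsed or is incomplete."""


class ValidationError(ValueError):
    """Raised when a ParameterSet violates a model invariant."""


@dataclass(frozen=True)
class CIValue:
    """Point estimate with a 95% confidence interval."""

    value: float
    lo: float
    hi: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.value, self.lo, self.hi)


@dataclass(frozen=True)
class MeanSE:
    mean: float
    se: float


@dataclass(frozen=True)
class EventCount:
    """Event numerator/denominator; ``p`` is the implied proportion.

    Configuration files must give integer counts; probabilistic draws may
    carry a fractional effective numerator at the same denominator.
    """

    events: float
    n: int

    @property
    def p(self) -> float:
        return self.events / self.n


@dataclass(frozen=True)
class TransfusionUse:
    given: EventCount
    units: MeanSE  # mean units conditional on receiving the product


@dataclass(frozen=True)
class ArmResourceUse:
    """Resource use over the 28-day trial period for one arm."""

    total_los_days: MeanSE
    icu_days: MeanSE
    procedures: dict[str, EventCount]
    transfusions: dict[str, TransfusionUse]


@dataclass(frozen=True)
class TrialCurveSpec:
    shape: str = "geometric"  # geometric | uniform
    ratio: float = 0.9


@dataclass(frozen=True)
class LifeTableSpec:
    source: str = "packaged"  # packaged | file | gompertz_makeham
    path: str | None = None
    makeham: float = 2.0e-4
    gompertz_a: float = 1.25e-5
    gompertz_b: float = 0.104


@dataclass(frozen=True)
class UtilityDecrement:
    min_age: float
    decrement: float


@dataclass(frozen=True)
class PostDischargeCosts:
    year1: float
    year2: float
    year3: float
    year4_plus_fraction: float

    @property
    def year4_plus(self) -> float:
        return self.year3 * self.year4_plus_fraction


@dataclass(frozen=True)
class UnitCosts:
    bed_day: float
    icu_day: float
    procedures: dict[str, float]
    transfusions: dict[str, float]


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated model parameterisation (GBP 2021)."""

    # run settings
    start_age: float
    horizon_age: float
    discount_rate_costs: float
    discount_rate_qalys: float
    wtp_threshold: float
    half_cycle_correction: bool
    discount_timing: str  # end | start
    trial_curve: TrialCurveSpec
    life_table: LifeTableSpec
    # mortality
    smr_y1: CIValue
    smr_y2plus: CIValue
    rr_mortality: CIValue
    risk28: EventCount
    # utilities
    utility_survivor: CIValue
    utility_decrements: tuple[UtilityDecrement, ...]
    # costs
    txa_admin_components: dict[str, float]
    unit_costs: UnitCosts
    postdischarge: PostDischargeCosts
    # per-arm resource use
    resource_use: dict[str, ArmResourceUse]
    # PSA settings
    psa_n: int
    psa_cost_se_fraction: float
    seed: int

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: dict[str, Any]) -> "ParameterSet":
        try:
            return cls._from_dict(cfg)
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"incomplete or malformed configuration: {exc}") from exc

    @classmethod
    def _from_dict(cls, cfg: dict[str, Any]) -> "ParameterSet":
        def ci(d: dict) -> CIValue:
            return CIValue(float(d["value"]), float(d["ci"][0]), float(d["ci"][1]))

        def mse(d: dict) -> MeanSE:
            return MeanSE(float(d["mean"]), float(d["se"]))

        def cnt(d: dict) -> EventCount:
            return EventCount(int(d["events"]), int(d["n"]))

        model = cfg["model"]
        mort = cfg["mortality"]
        util = cfg["utilities"]
        costs = cfg["costs"]
        ru = cfg["resource_use"]
        psa = cfg["psa"]
        lt = cfg.get("life_table", {}) or {}
        gm = lt.get("gompertz_makeham", {}) or {}

        arms = {}
        for arm in ARMS:
            a = ru[arm]
            arms[arm] = ArmResourceUse(
                total_los_days=mse(a["total_los_days"]),
                icu_days=mse(a["icu_days"]),
                procedures={k: cnt(a["procedures"][k]) for k in PROCEDURE_TYPES},
                transfusions={
                    k: TransfusionUse(
                        given=cnt(a["transfusions"][k]),
                        units=mse(a["transfusions"][k]["units"]),
                    )
                    for k in TRANSFUSION_TYPES
                },
            )

        return cls(
            start_age=float(model["start_age"]),
            horizon_age=float(model["horizon_age"]),
            discount_rate_costs=float(model["discount_rate_costs"]),
            discount_rate_qalys=float(model["discount_rate_qalys"]),
            wtp_threshold=float(model["wtp_threshold"]),
            half_cycle_correction=bool(model["half_cycle_correction"]),
            discount_timing=str(model["discount_timing"]),
            trial_curve=TrialCurveSpec(
                shape=str(model["trial_curve"]["shape"]),
                ratio=float(model["trial_curve"]["ratio"]),
            ),
            life_table=LifeTableSpec(
                source=str(lt.get("source", "packaged")),
                path=lt.get("path"),
                makeham=float(gm.get("makeham", 2.0e-4)),
                gompertz_a=float(gm.get("a", 1.25e-5)),
                gompertz_b=float(gm.get("b", 0.104)),
            ),
            smr_y1=ci(mort["smr_year1"]),
            smr_y2plus=ci(mort["smr_year2plus"]),
            rr_mortality=ci(mort["rr_mortality"]),
            risk28=cnt(mort["risk28"]),
            utility_survivor=ci(util["survivor"]),
            utility_decrements=tuple(
                UtilityDecrement(float(d["min_age"]), float(d["decrement"]))
                for d in util["decrements"]
            ),
            txa_admin_components={k: float(v) for k, v in costs["txa_admin"].items()},
            unit_costs=UnitCosts(
                bed_day=float(costs["unit"]["bed_day"]),
                icu_day=float(costs["unit"]["icu_day"]),
                procedures={
                    k: float(costs["unit"]["procedures"][k]) for k in PROCEDURE_TYPES
                },
                transfusions={
                    k: float(costs["unit"]["transfusions"][k])
                    for k in TRANSFUSION_TYPES
                },
            ),
            postdischarge=PostDischargeCosts(
                year1=float(costs["post_discharge"]["year1"]),
                year2=float(costs["post_discharge"]["year2"]),
                year3=float(costs["post_discharge"]["year3"]),
                year4_plus_fraction=float(
                    costs["post_discharge"]["year4_plus_fraction"]
                ),
            ),
            resource_use=arms,
            psa_n=int(psa["n_draws"]),
            psa_cost_se_fraction=float(psa["cost_se_fraction"]),
            seed=int(psa["seed"]),
        )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        """Dictionary mirroring the YAML configuration schema."""

        def ci(v: CIValue) -> dict:
            return {"value": v.value, "ci": [v.lo, v.hi]}

        def mse(v: MeanSE) -> dict:
            return {"mean": v.mean, "se": v.se}

        def cnt(v: EventCount) -> dict:
            return {"events": v.events, "n": v.n}

        ru = {}
        for arm in ARMS:
            a = self.resource_use[arm]
            ru[arm] = {
                "total_los_days": mse(a.total_los_days),
                "icu_days": mse(a.icu_days),
                "procedures": {k: cnt(a.procedures[k]) for k in PROCEDURE_TYPES},
                "transfusions": {
                    k: {**cnt(a.transfusions[k].given), "units": mse(a.transfusions[k].units)}
                    for k in TRANSFUSION_TYPES
                },
            }

        return {
            "model": {
                "start_age": self.start_age,
                "horizon_age": self.horizon_age,
                "discount_rate_costs": self.discount_rate_costs,
                "discount_rate_qalys": self.discount_rate_qalys,
                "wtp_threshold": self.wtp_threshold,
                "half_cycle_correction": self.half_cycle_correction,
                "discount_timing": self.discount_timing,
                "trial_curve": {
                    "shape": self.trial_curve.shape,
                    "ratio": self.trial_curve.ratio,
                },
            },
            "life_table": {
                "source": self.life_table.source,
                "path": self.life_table.path,
                "gompertz_makeham": {
                    "makeham": self.life_table.makeham,
                    "a": self.life_table.gompertz_a,
                    "b": self.life_table.gompertz_b,
                },
            },
            "mortality": {
                "smr_year1": ci(self.smr_y1),
                "smr_year2plus": ci(self.smr_y2plus),
                "rr_mortality": ci(self.rr_mortality),
                "risk28": cnt(self.risk28),
            },
            "utilities": {
                "survivor": ci(self.utility_survivor),
                "decrements": [
                    {"min_age": d.min_age, "decrement": d.decrement}
                    for d in self.utility_decrements
                ],
            },
            "costs": {
                "txa_admin": dict(self.txa_admin_components),
                "unit": {
                    "bed_day": self.unit_costs.bed_day,
                    "icu_day": self.unit_costs.icu_day,
                    "procedures": dict(self.unit_costs.procedures),
                    "transfusions": dict(self.unit_costs.transfusions),
                },
                "post_discharge": {
                    "year1": self.postdischarge.year1,
                    "year2": self.postdischarge.year2,
                    "year3": self.postdischarge.year3,
                    "year4_plus_fraction": self.postdischarge.year4_plus_fraction,
                },
            },
            "resource_use": ru,
            "psa": {
                "n_draws": self.psa_n,
                "cost_se_fraction": self.psa_cost_se_fraction,
                "seed": self.seed,
            },
        }

    def to_json(self, path: str | Path | None = None, **kwargs: Any) -> str:
        """JSON export of the validated parameter set (provenance logging)."""
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def with_overrides(self, overrides: dict[str, Any]) -> "ParameterSet":
        """Return a copy with dotted-path keys replaced.

        ``{"mortality.rr_mortality.value": 0.92}`` replaces a single leaf in
        the configuration-schema representation of the parameter set.
        """
        cfg = copy.deepcopy(self.to_dict())
        for path, value in overrides.items():
            node = cfg
            parts = path.split(".")
            for part in parts[:-1]:
                if part not in node:
                    raise KeyError(f"unknown parameter path: {path!r}")
                node = node[part]
            if parts[-1] not in node:
                raise KeyError(f"unknown parameter path: {path!r}")
            node[parts[-1]] = value
        ps = ParameterSet.from_dict(cfg)
        raise_on_violations(ps)
        return ps

    @property
    def risk28_value(self) -> float:
        """28-day probability of death in the no-TXA arm (548/5981 -> 0.0916)."""
        return self.risk28.p


@dataclass(frozen=True)
class Violation:
    """One invariant violation: which field, what value, which rule."""

    field: str
    value: Any
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r}: {self.rule}"


def _check_ci(name: str, v: CIValue, out: list[Violation]) -> None:
    if not v.lo <= v.value <= v.hi:
        out.append(Violation(name, v.as_tuple(), "CI must satisfy lo <= point <= hi"))


def _check_count(name: str, c: EventCount, out: list[Violation]) -> None:
    if c.n <= 0:
        out.append(Violation(name, (c.events, c.n), "denominator must be positive"))
    elif not 0 <= c.events <= c.n:
        out.append(Violation(name, (c.events, c.n), "events must lie in [0, n]"))


def validate(params: ParameterSet) -> list[Violation]:
    """Check every model invariant; empty list means the set is valid."""
    out: list[Violation] = []

    for name, v in [
        ("smr_y1", params.smr_y1),
        ("smr_y2plus", params.smr_y2plus),
        ("rr_mortality", params.rr_mortality),
        ("utility_survivor", params.utility_survivor),
    ]:
        _check_ci(name, v, out)
    for name, v in [("smr_y1", params.smr_y1), ("smr_y2plus", params.smr_y2plus)]:
        if v.value <= 0:
            out.append(Violation(name, v.value, "SMR must be positive"))
    if params.rr_mortality.value <= 0:
        out.append(Violation("rr_mortality", params.rr_mortality.value, "RR must be positive"))

    _check_count("risk28", params.risk28, out)

    u = params.utility_survivor.value
    if not 0.0 < u <= 1.0:
        out.append(Violation("utility_survivor", u, "utility must lie in (0, 1]"))
    for d in params.utility_decrements:
        if d.decrement < 0 or u - d.decrement < 0:
            out.append(
                Violation("utility_decrements", d.decrement,
                          "decrement must keep effective utility in [0, 1]")
            )

    for name, r in [
        ("discount_rate_costs", params.discount_rate_costs),
        ("discount_rate_qalys", params.discount_rate_qalys),
    ]:
        if not 0.0 <= r <= 0.10:
            out.append(Violation(name, r, "discount rate must lie in [0, 0.10]"))

    if params.wtp_threshold < 0:
        out.append(Violation("wtp_threshold", params.wtp_threshold, "must be non-negative"))
    if params.horizon_age <= params.start_age:
        out.append(
            Violation("horizon_age", params.horizon_age, "must exceed start_age")
        )
    if params.discount_timing not in ("end", "start"):
        out.append(
            Violation("discount_timing", params.discount_timing, "must be 'end' or 'start'")
        )
    if params.trial_curve.shape not in ("geometric", "uniform"):
        out.append(
            Violation("trial_curve.shape", params.trial_curve.shape,
                      "must be 'geometric' or 'uniform'")
        )

    for k, v in params.txa_admin_components.items():
        if v < 0:
            out.append(Violation(f"txa_admin.{k}", v, "cost component must be >= 0"))
    for grp, costs in [
        ("unit.procedures", params.unit_costs.procedures),
        ("unit.transfusions", params.unit_costs.transfusions),
    ]:
        for k, v in costs.items():
            if v < 0:
                out.append(Violation(f"{grp}.{k}", v, "unit cost must be >= 0"))
    for name, v in [
        ("unit.bed_day", params.unit_costs.bed_day),
        ("unit.icu_day", params.unit_costs.icu_day),
        ("post_discharge.year1", params.postdischarge.year1),
        ("post_discharge.year2", params.postdischarge.year2),
        ("post_discharge.year3", params.postdischarge.year3),
        ("post_discharge.year4_plus_fraction", params.postdischarge.year4_plus_fraction),
    ]:
        if v < 0:
            out.append(Violation(name, v, "must be >= 0"))

    for arm in ARMS:
        a = params.resource_use[arm]
        pre = f"resource_use.{arm}"
        for name, m in [
            (f"{pre}.total_los_days", a.total_los_days),
            (f"{pre}.icu_days", a.icu_days),
        ]:
            if m.mean < 0:
                out.append(Violation(name, m.mean, "mean must be >= 0"))
            if m.se < 0:
                out.append(Violation(name, m.se, "SE must be >= 0"))
        if a.icu_days.mean > a.total_los_days.mean:
            out.append(
                Violation(f"{pre}.icu_days", a.icu_days.mean,
                          "mean ICU days cannot exceed mean total length of stay")
            )
        for k, c in a.procedures.items():
            _check_count(f"{pre}.procedures.{k}", c, out)
        for k, t in a.transfusions.items():
            _check_count(f"{pre}.transfusions.{k}", t.given, out)
            if t.units.mean < 0 or t.units.se < 0:
                out.append(
                    Violation(f"{pre}.transfusions.{k}.units",
                              (t.units.mean, t.units.se), "must be >= 0")
                )

    if params.psa_n < 1:
        out.append(Violation("psa.n_draws", params.psa_n, "must be >= 1"))
    if params.psa_cost_se_fraction < 0:
        out.append(Violation("psa.cost_se_fraction", params.psa_cost_se_fraction,
                             "must be >= 0"))

    return out


def raise_on_violations(params: ParameterSet) -> None:
    violations = validate(params)
    if violations:
        raise ValidationError(
            "invalid parameter set: " + "; ".join(str(v) for v in violations)
        )


def _default_config_dict() -> dict[str, Any]:
    text = resources.files("txa_cea.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def default_parameters() -> ParameterSet:
    """The shipped base-case parameterisation."""
    ps = ParameterSet.from_dict(_default_config_dict())
    raise_on_violations(ps)
    return ps


def load_config(path: str | Path, use_defaults: bool = False) -> ParameterSet:
    """Load and validate a configuration file.

    Parameters
    ----------
    path
        YAML file following the documented schema.
    use_defaults
        When true, keys missing from the file fall back to the shipped
        defaults; otherwise an incomplete file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" (line {mark.line + 1}, column {mark.column + 1})" if mark else ""
        raise ConfigError(f"cannot parse {path}{where}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path} does not contain a configuration mapping")
    if use_defaults:
        cfg = _deep_merge(_default_config_dict(), cfg)
    ps = ParameterSet.from_dict(cfg)
    raise_on_violations(ps)
    return ps
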