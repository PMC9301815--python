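"""Synthetic patient-level trial data and parameter re-estimation.

The deposited trial data are not openly downloadable, so this module closes
the loop from raw-data emulation to model inputs: :func:`simulate_trial`
generates two-arm patient records with the statistical structure the model
assumes (28-day deaths following the configured daily curve, gamma lengths of
stay, Bernoulli procedure indicators, zero-inflated transfusion unit counts),
and :func:`estimate_parameters` recovers the corresponding summary inputs —
28-day risk, mortality risk ratio with log-scale CI, resource-use means and
event counts — in the exact shape the parameter store expects.

Transfusion "mean units" are conditional on receiving the product, matching
the costing arithmetic (cost = probability x mean units x unit price); the
unconditional per-patient mean is therefore probability x mean.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import (
    ARMS,
    PROCEDURE_TYPES,
    TRANSFUSION_TYPES,
    ParameterSet,
    default_parameters,
)
from .survival import default_shape, make_trial_curve

Z95 = 1.959963984540054

CSV_COLUMNS = (
    ["id", "arm", "died_28day", "death_day", "total_los", "icu_days"]
    + [f"proc_{k}" for k in PROCEDURE_TYPES]
    + [f"tx_{k}_given" for k in TRANSFUSION_TYPES]
    + [f"tx_{k}_units" for k in TRANSFUSION_TYPES]
)


def _gamma(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if mean <= 0 or sd <= 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    return rng.gamma(shape, sd**2 / mean, size)


def simulate_trial(
    truth: ParameterSet | None = None,
    n_per_arm: int = 6000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate patient records for both arms under ``truth``.

    Control-arm deaths follow the configured 28-day daily curve; the
    treatment arm scales the cumulative risk by the mortality risk ratio with
    the same daily shape. ICU days are redrawn until they do not exceed the
    total length of stay.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    if truth is None:
        truth = default_parameters()
    rng = np.random.default_rng(seed)
    shape = default_shape(truth.trial_curve.shape, truth.trial_curve.ratio)

    frames = []
    for arm in ARMS:
        use = truth.resource_use[arm]
        risk = truth.risk28_value
        if arm == "txa":
            risk *= truth.rr_mortality.value
        curve = make_trial_curve(risk, shape)

        died = rng.random(n_per_arm) < risk
        if risk > 0:
            day_probs = curve.unconditional / curve.cumulative_risk
            days = rng.choice(np.arange(1, 29), size=n_per_arm, p=day_probs)
        else:
            days = np.zeros(n_per_arm, dtype=int)
        death_day = np.where(died, days, 0)

        los = _gamma(rng, use.total_los_days.mean, use.total_los_days.se, n_per_arm)
        icu = _gamma(rng, use.icu_days.mean, use.icu_days.se, n_per_arm)
        for _ in range(1000):
            over = icu > los
            if not over.any():
                break
            icu[over] = _gamma(
                rng, use.icu_days.mean, use.icu_days.se, int(over.sum())
            )
        icu = np.minimum(icu, los)  # guard: truncate any stragglers

        rec: dict[str, np.ndarray] = {
            "id": np.arange(n_per_arm),
            "arm": np.full(n_per_arm, arm),
            "died_28day": died,
            "death_day": death_day,
            "total_los": los,
            "icu_days": icu,
        }
        for k in PROCEDURE_TYPES:
            rec[f"proc_{k}"] = rng.random(n_per_arm) < use.procedures[k].p
        for k in TRANSFUSION_TYPES:
            t = use.transfusions[k]
            given = rng.random(n_per_arm) < t.given.p
            units = _gamma(rng, t.units.mean, t.units.se, n_per_arm)
            rec[f"tx_{k}_given"] = given
            rec[f"tx_{k}_units"] = np.where(given, units, 0.0)
        frames.append(pd.DataFrame(rec))

    df = pd.concat(frames, ignore_index=True)
    df["id"] = np.arange(len(df))
    return df[CSV_COLUMNS]


def write_trial_csv(records: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write records with a metadata comment line recording the seed."""
    buf = io.StringIO()
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    records.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    return df


@dataclass(frozen=True)
class EstimatedParameters:
    """Trial summaries re-estimated from patient records.

    ``risk28`` and the per-arm resource blocks slot directly into the
    parameter-store schema; ``rr`` carries a log-scale 95% CI.
    """

    risk28_events: int
    risk28_n: int
    rr: float | None
    rr_ci: tuple[float, float] | None
    rr_se_log: float | None
    resource_use: dict[str, dict]

    @property
    def risk28(self) -> float:
        return self.risk28_events / self.risk28_n

    def to_overrides(self) -> dict[str, object]:
        """Dotted-path overrides updating a ParameterSet with the estimates."""
        out: dict[str, object] = {
            "mortality.risk28": {"events": self.risk28_events, "n": self.risk28_n},
        }
        if self.rr is not None:
            out["mortality.rr_mortality"] = {
                "value": self.rr,
                "ci": [self.rr_ci[0], self.rr_ci[1]],
            }
        for arm in ARMS:
            out[f"resource_use.{arm}"] = self.resource_use[arm]
        return out

    def apply_to(self, params: ParameterSet) -> ParameterSet:
        return params.with_overrides(self.to_overrides())


def estimate_parameters(records: pd.DataFrame) -> EstimatedParameters:
    """Recover model input summaries from patient-level records."""
    arms_present = set(records["arm"].unique())
    if not {"txa", "no_txa"} <= arms_present:
        raise ValueError(f"need both arms, found {sorted(arms_present)}")

    by_arm = {arm: records[records["arm"] == arm] for arm in ARMS}
    deaths = {arm: int(by_arm[arm]["died_28day"].sum()) for arm in ARMS}
    n = {arm: len(by_arm[arm]) for arm in ARMS}

    rr = rr_ci = rr_se = None
    if deaths["no_txa"] == 0:
        # risk ratio undefined without control-arm events; flag by leaving None
        pass
    elif deaths["txa"] > 0:
        p_c = deaths["no_txa"] / n["no_txa"]
        p_t = deaths["txa"] / n["txa"]
        rr = p_t / p_c
        rr_se = float(
            np.sqrt(
                1 / deaths["txa"] - 1 / n["txa"] + 1 / deaths["no_txa"] - 1 / n["no_txa"]
            )
        )
        rr_ci = (
            float(rr * np.exp(-Z95 * rr_se)),
            float(rr * np.exp(Z95 * rr_se)),
        )

    resource = {}
    for arm in ARMS:
        d = by_arm[arm]
        m = len(d)
        block: dict[str, object] = {
            "total_los_days": {
                "mean": float(d["total_los"].mean()),
                "se": float(d["total_los"].std(ddof=1) / np.sqrt(m)),
            },
            "icu_days": {
                "mean": float(d["icu_days"].mean()),
                "se": float(d["icu_days"].std(ddof=1) / np.sqrt(m)),
            },
            "procedures": {
                k: {"events": int(d[f"proc_{k}"].sum()), "n": m}
                for k in PROCEDURE_TYPES
            },
        }
        transf = {}
        for k in TRANSFUSION_TYPES:
            given = d[f"tx_{k}_given"].astype(bool)
            units = d.loc[given, f"tx_{k}_units"]
            transf[k] = {
                "events": int(given.sum()),
                "n": m,
                "units": {
                    "mean": float(units.mean()) if len(units) else 0.0,
                    "se": float(units.std(ddof=1) / np.sqrt(len(units)))
                    if len(units) > 1
                    else 0.0,
                },
            }
        block["transfusions"] = transf
        resource[arm] = block

    return EstimatedParameters(
        risk28_events=deaths["no_txa"],
        risk28_n=n["no_txa"],
        rr=rr,
        rr_ci=rr_ci,
        rr_se_log=rr_se,
        resource_use=resource,
    )
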