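"""Config-driven campaigns over random homeostatic models.

A campaign generates ``n_models`` random models of one class, resolves each
model's stopping time (saturation horizon ``20/alpha_min`` for GIA, the 98%
extinction time for GPA), simulates a clone ensemble per model, computes the
clonal statistics and distances to the universal reference laws, applies the
exclusion rule (models whose final surviving mean is below two are dropped
from ensemble summaries), and writes CSV tables plus a JSON manifest with
every seed and config needed to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .generate import GeneratorConfig, canonical, random_homeostatic, rescale_renewing
from .laws import exp_unit_mean, normal_std
from .network import decompose
from .simulate import StoppingRule, resolve_stopping, simulate_ensemble
from .stats import (
    CloneSizeStatistics,
    ensemble_percentile_bands,
    ks_distance,
    rescaled_distribution,
    standardized_distribution,
)

__all__ = ["CampaignConfig", "CampaignResult", "run_campaign", "reproduce_figure"]

#: models whose final surviving mean is below this are excluded from summaries
DEFAULT_MIN_FINAL_MEAN = 2.0


@dataclass(frozen=True)
class CampaignConfig:
    master_seed: int
    class_target: str = "GPA"
    n_models: int = 20
    clones_per_model: int = 2000
    max_states: int = 6
    density: float = 0.5
    rate_low: float = 0.1
    rate_high: float = 1.0
    lambda_hat_target: float | None = None
    extinction_quantile: float = 0.98
    min_final_mean: float = DEFAULT_MIN_FINAL_MEAN
    pilot_clones: int = 2000

    def generator_config(self, k: int) -> GeneratorConfig:
        # per-model seeds derive deterministically from the master seed
        ss = np.random.SeedSequence((self.master_seed, k))
        rng = np.random.default_rng(ss)
        n_states = None
        if self.max_states is not None:
            n_states = int(rng.integers(3, self.max_states + 1))
        return GeneratorConfig(
            seed=int(ss.generate_state(1)[0] % 2**31),
            class_target=self.class_target,
            n_states=n_states,
            density=self.density,
            rate_low=self.rate_low,
            rate_high=self.rate_high,
            lambda_hat_target=self.lambda_hat_target,
        )


@dataclass
class CampaignResult:
    config: CampaignConfig
    records: list[dict]
    curves: pd.DataFrame  # per-model n_bar_s(t) etc.
    samples: dict[str, np.ndarray]  # model_id -> rescaled sample at tau
    samples_std: dict[str, np.ndarray]  # model_id -> standardised sample at tau
    excluded: list[str]
    failed: list[dict]

    @property
    def retained(self) -> list[str]:
        return [r["model_id"] for r in self.records if not r["excluded"]]

    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "models": self.records,
            "excluded": self.excluded,
            "failed": self.failed,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.curves.to_csv(out / "statistics.csv", index=False)
        bands = self.distribution_bands()
        if bands is not None:
            bands.to_csv(out / "bands.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)

    def distribution_bands(self, levels=(5.0, 50.0, 95.0), standardised=None):
        """Cross-model percentile envelope of the ECDFs of the rescaled (or
        standardised) clone-size samples at final time."""
        if standardised is None:
            standardised = self.config.class_target == "GIA" and self.config.lambda_hat_target
        pool = self.samples_std if standardised else self.samples
        curves = []
        for mid in self.retained:
            s = np.sort(pool[mid])
            curves.append((s, np.arange(1, s.size + 1) / s.size))
        if not curves:
            return None
        lo = min(c[0][0] for c in curves)
        hi = max(c[0][-1] for c in curves)
        grid = np.linspace(lo, hi, 201)
        return ensemble_percentile_bands(curves, grid, levels)


def _model_seed(master_seed: int, k: int, purpose: int) -> tuple:
    return (master_seed, k, purpose)


def run_campaign(config: CampaignConfig, progress: bool = False) -> CampaignResult:
    """Generate, simulate and summarise ``n_models`` random models.

    Per-model failures (homeostasis tuning, runaway populations, extinct
    ensembles) are logged and skipped; the campaign raises only when more
    than half of the models fail.
    """
    records: list[dict] = []
    rows: list[pd.DataFrame] = []
    samples: dict[str, np.ndarray] = {}
    samples_std: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    failed: list[dict] = []
    law_exp = exp_unit_mean()
    law_norm = normal_std()

    for k in range(config.n_models):
        model_id = f"{config.class_target.lower()}-{config.master_seed}-{k:03d}"
        try:
            gen_cfg = config.generator_config(k)
            model, decomp = random_homeostatic(gen_cfg)
            init = model.states[decomp.R_states[0]]
            mode = "gia_default" if decomp.model_class == "GIA" else "gpa_default"
            rule = resolve_stopping(
                model,
                decomp,
                StoppingRule(mode, extinction_quantile=config.extinction_quantile),
                pilot_seed=gen_cfg.seed,
                pilot_clones=config.pilot_clones,
                initial_state=init,
            )
            ens = simulate_ensemble(
                model, config.clones_per_model, init, rule,
                seed=_model_seed(config.master_seed, k, 3),
            )
            stats = CloneSizeStatistics.from_ensemble(ens)
            x = rescaled_distribution(ens, -1)
            xt = standardized_distribution(ens, -1)
            ks_exp = ks_distance(x, law_exp)
            ks_norm = ks_distance(xt, law_norm)
            final_mean = float(stats.n_bar_s[-1])
            is_excluded = final_mean < config.min_final_mean
            eff = decomp.effective.as_dict() if decomp.effective else None
            records.append(
                {
                    "model_id": model_id,
                    "generator_seed": gen_cfg.seed,
                    "n_states": model.n_states,
                    "model_class": decomp.model_class,
                    "mu": [float(v) for v in decomp.mu],
                    "effective_rates": eff,
                    "tau": float(rule.t_max),
                    "final_mean": final_mean,
                    "ks_exp": float(ks_exp),
                    "ks_norm": float(ks_norm),
                    "excluded": is_excluded,
                }
            )
            df = pd.DataFrame(
                {
                    "model_id": model_id,
                    "t": stats.times,
                    "n_bar_s": stats.n_bar_s,
                    "sigma_n": stats.sigma_n,
                    "extinct_frac": stats.extinct_fraction,
                    "ks_exp": ks_exp,
                    "ks_norm": ks_norm,
                }
            )
            rows.append(df)
            if is_excluded:
                excluded.append(model_id)
            else:
                samples[model_id] = x
                samples_std[model_id] = xt
            if progress:
                print(f"[{model_id}] class={decomp.model_class} tau={rule.t_max:.3g} "
                      f"n_bar_s={final_mean:.3g} ks_exp={ks_exp:.3f} ks_norm={ks_norm:.3f}")
        except Exception as exc:  # per-model failure: log and continue
            failed.append({"model_id": model_id, "error": f"{type(exc).__name__}: {exc}"})
            if progress:
                print(f"[{model_id}] FAILED: {exc}")
    if len(failed) > config.n_models / 2:
        raise RuntimeError(
            f"campaign failed: {len(failed)}/{config.n_models} models errored; "
            f"first error: {failed[0]['error']}"
        )
    curves = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return CampaignResult(config, records, curves, samples, samples_std, excluded, failed)


def reproduce_figure(
    which: str,
    master_seed: int = 0,
    scale: float = 1.0,
    out_dir=None,
    progress: bool = False,
):
    """Run the campaign behind one of the summary figures at desk scale.

    ``fig2`` — surviving-mean curves for GIA (saturating) and GPA (growing);
    ``fig3`` — rescaled clone-size distributions at final time against the
    unit-mean Exponential; ``fig4`` — standardised distributions of GIA
    models rescaled to fast renewing dynamics (``lambda_hat_R = 30``)
    against the standard Normal, plus a sweep of the illustrative two-state
    GIA model over ``lambda_hat_R`` in {1, 5, 30}.
    ``scale`` multiplies the number of models and clones.
    """
    n_models = max(2, int(round(20 * scale)))
    out = {}
    if which in ("fig2", "fig3"):
        gia = run_campaign(
            CampaignConfig(master_seed=master_seed, class_target="GIA",
                           n_models=n_models,
                           clones_per_model=max(200, int(round(2000 * scale)))),
            progress=progress,
        )
        gpa = run_campaign(
            CampaignConfig(master_seed=master_seed, class_target="GPA",
                           n_models=n_models,
                           clones_per_model=max(500, int(round(20000 * scale)))),
            progress=progress,
        )
        out = {"GIA": gia, "GPA": gpa}
    elif which == "fig4":
        gia = run_campaign(
            CampaignConfig(master_seed=master_seed, class_target="GIA",
                           n_models=n_models,
                           clones_per_model=max(200, int(round(2000 * scale))),
                           lambda_hat_target=30.0),
            progress=progress,
        )
        sweep = {}
        for lhat in (1.0, 5.0, 30.0):
            model = canonical("GIA0", lam1=1.0, lam2=0.5, gamma=1.0)
            d = decompose(model)
            scaled = rescale_renewing(model, lhat / d.effective.lambda_hat_R, d)
            rule = resolve_stopping(scaled, decompose(scaled), StoppingRule("gia_default"))
            ens = simulate_ensemble(
                scaled,
                max(500, int(round(5000 * scale))),
                "X1",
                rule,
                seed=(master_seed, int(lhat * 1000)),
            )
            xt = standardized_distribution(ens, -1)
            sweep[lhat] = {
                "ks_norm": float(ks_distance(xt, normal_std())),
                "ks_exp_rescaled": float(ks_distance(rescaled_distribution(ens, -1), exp_unit_mean())),
            }
        out = {"GIA": gia, "sweep": sweep}
    else:
        raise ValueError(f"unknown figure {which!r}; expected fig2, fig3 or fig4")
    if out_dir is not None:
        base = Path(out_dir)
        for name, res in out.items():
            if isinstance(res, CampaignResult):
                res.write(base / name)
            else:
                base.mkdir(parents=True, exist_ok=True)
                with open(base / "sweep.json", "w") as fh:
                    json.dump(res, fh, indent=2, sort_keys=True)
    return out
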