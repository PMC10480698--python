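"""End-to-end orchestration: data -> SDT fits -> hierarchical model -> ordinal models.

A single YAML/dict config drives the whole analysis; every stage writes tidy
CSV/JSON artifacts into the output directory and records its status in a
:class:`RunManifest`.  Stage order mirrors the analysis narrative: per-subject
signal-detection fits, the hierarchical within-subject M-ratio model with its
Savage-Dickey Bayes factor, per-question ordinal regressions, and two
robustness variants (refit after excluding endorsers of a flagged conspiracy
statement; ordinal control models adding science-domain metacognition as a
covariate).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort, hmeta, ordinal, sdt_core, survey_io

__all__ = ["RunManifest", "run_pipeline", "report"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    out_dir: str
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, status: str, **info):
        self.stages[stage] = {"status": status, **info}

    def to_json(self, path=None):
        path = path or Path(self.out_dir) / "manifest.json"
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))
        return path


def _mcmc_presets(name: str):
    if name == "paper":
        return hmeta.PAPER_MCMC, ordinal.ORDINAL_PAPER_MCMC
    if name == "test":
        return hmeta.TEST_MCMC, ordinal.ORDINAL_TEST_MCMC
    raise ValueError(f"unknown MCMC preset {name!r}")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def fit_sdt_table(counts: dict) -> tuple[pd.DataFrame, dict, dict]:
    """Per-respondent x domain type-1 and meta-d' MLE fits as a tidy frame."""
    rows, type1, metad = [], {}, {}
    for (rid, dom), cc in sorted(counts.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        t1 = sdt_core.estimate_type1(cc.counts)
        mf = sdt_core.fit_metad_mle(cc.counts, t1)
        type1[(rid, dom)] = t1
        metad[(rid, dom)] = mf
        rows.append({
            "respondent_id": rid, "domain": dom, "d_prime": t1.d_prime,
            "c": t1.c, "meta_d": mf.meta_d, "m_ratio": mf.m_ratio,
            "log_m_ratio": mf.log_m_ratio, "loglik": mf.loglik,
            "flags": ";".join(mf.flags),
        })
    return pd.DataFrame(rows), type1, metad


def _hier_summary_payload(post, bf):
    summ = post.mratio_summary()
    return {
        "m_ratio": {k: v for k, v in summ.items() if k != "delta"},
        "delta": summ["delta"],
        "bayes_factor": {
            "bf10": bf.bf10, "delta_prior": list(bf.prior),
            "is_lower_bound": bf.is_lower_bound,
            "posterior_density_normal": bf.posterior_density_normal,
            "posterior_density_kde": bf.posterior_density_kde,
        },
        "rhat": post.rhat, "ess": post.ess, "warnings": post.warnings,
        "n_draws": post.n_draws,
        "dropped_subjects": len(post.dropped_subjects),
    }


def run_pipeline(config, out_dir=None) -> RunManifest:
    """Execute the full analysis; on stage failure, downstream stages are skipped."""
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 1))
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(config_hash=cfg_hash, seed=seed, out_dir=str(out))
    hier_mcmc, ord_mcmc = _mcmc_presets(cfg.get("mcmc_preset", "test"))
    hier_mcmc = dataclasses.replace(hier_mcmc, seed=seed,
                                    **cfg.get("mcmc_override", {}))
    ord_mcmc = dataclasses.replace(ord_mcmc, seed=seed,
                                   **cfg.get("mcmc_override", {}))

    # ---- stage: data -------------------------------------------------------
    truth = None
    try:
        if "simulate" in cfg:
            sim = dict(cfg["simulate"])
            preset = cohort.paper_shape_preset(
                n_subjects=int(sim.pop("n_subjects", 1689)), seed=seed)
            cc = dataclasses.replace(preset, **sim) if sim else preset
            responses, attitudes, truth = cohort.generate_cohort(cc, seed=seed)
            responses.df.to_csv(out / "responses.csv", index=False)
            attitudes.df.to_csv(out / "attitudes.csv", index=False)
            truth.to_json(out / "ground_truth.json")
            manifest.outputs["responses"] = str(out / "responses.csv")
            manifest.outputs["ground_truth"] = str(out / "ground_truth.json")
        else:
            inp = cfg["input"]
            responses = survey_io.read_responses(inp["responses"],
                                                 schema=inp.get("schema"))
            attitudes = None
            if "attitudes" in inp:
                att_df = pd.read_csv(inp["attitudes"])
                attitudes = survey_io.AttitudeTable(
                    df=att_df, outcomes=inp.get("outcomes", {}),
                    group_vars=inp.get("group_vars", []),
                )
        manifest.record("data", "ok", respondents=int(len(responses.respondents)))
    except Exception as e:  # noqa: BLE001 - manifest captures the failure
        manifest.record("data", "failed", error=repr(e))
        manifest.to_json()
        return manifest

    # ---- stage: sdt --------------------------------------------------------
    try:
        counts = survey_io.tabulate_counts(responses)
        sdt_df, type1, _ = fit_sdt_table(counts)
        sdt_df.to_csv(out / "sdt_fits.csv", index=False)
        manifest.outputs["sdt_fits"] = str(out / "sdt_fits.csv")
        mean_d = sdt_df.groupby("domain")["d_prime"].mean().to_dict()
        manifest.record("sdt", "ok", mean_d_prime=mean_d)
    except Exception as e:  # noqa: BLE001
        manifest.record("sdt", "failed", error=repr(e))
        manifest.to_json()
        return manifest

    # ---- stage: hierarchical ----------------------------------------------
    try:
        spec = hmeta.HierModelSpec(mcmc=hier_mcmc,
                                   **cfg.get("hier_priors", {}))
        post = hmeta.fit_hierarchical(counts, type1, spec)
        bf = hmeta.savage_dickey_bf(post, spec)
        payload = _hier_summary_payload(post, bf)
        (out / "hier_summary.json").write_text(json.dumps(payload, indent=2))
        manifest.outputs["hier_summary"] = str(out / "hier_summary.json")
        pd.DataFrame({k: post.flat(k) for k in post.draws}).to_csv(
            out / "hier_draws.csv", index=False)
        manifest.outputs["hier_draws"] = str(out / "hier_draws.csv")
        manifest.warnings.extend(post.warnings)
        manifest.record("hier", "ok", bf10=bf.bf10,
                        m_ratio={k: v["mean"]
                                 for k, v in payload["m_ratio"].items()})
    except Exception as e:  # noqa: BLE001
        manifest.record("hier", "failed", error=repr(e))
        manifest.to_json()
        return manifest

    # ---- stage: ordinal ----------------------------------------------------
    ord_results = {}
    try:
        if attitudes is None:
            manifest.record("ordinal", "skipped", reason="no attitude data")
        else:
            subj_mean = post.subject_mean()
            sdt_cov = pd.DataFrame({
                "respondent_id": post.subject_ids,
                "log_mratio": subj_mean[:, 1],
                "log_mratio_science": subj_mean[:, 0],
            })
            d_cov = sdt_df[sdt_df["domain"] == "covid"][
                ["respondent_id", "d_prime"]]
            data = attitudes.df.merge(sdt_cov, on="respondent_id").merge(
                d_cov, on="respondent_id")
            fixed = ("log_mratio", "d_prime", "age", "gender", "affected")
            for outcome, cats in attitudes.outcomes.items():
                for label, extra in (("main", ()), ("control_science_mratio",
                                                    ("log_mratio_science",))):
                    spec_o = ordinal.OrdinalModelSpec(
                        outcome=outcome, categories=tuple(cats),
                        fixed_effects=fixed + extra,
                        scale_2sd=("log_mratio", "d_prime", "age") + extra,
                        random_groups=tuple(attitudes.group_vars),
                        mcmc=ord_mcmc,
                    )
                    fit = ordinal.fit_ordinal(spec_o, data)
                    or_1sd = ordinal.odds_ratio(fit, "log_mratio", per="1sd")
                    mr = np.exp(data["log_mratio"])
                    grid = np.linspace(np.percentile(mr, 5),
                                       np.percentile(mr, 95), 25)
                    me = ordinal.marginal_effects(fit, "log_mratio", grid)
                    ord_results[(outcome, label)] = {
                        "fit": fit, "odds_ratio_1sd": or_1sd,
                        "pseudo_r2": ordinal.pseudo_r2(fit),
                        "marginal": me,
                    }
                    manifest.warnings.extend(fit.warnings)
            payload = {
                f"{outcome}:{label}": {
                    "odds_ratio_1sd": {k: v for k, v in
                                       res["odds_ratio_1sd"].items()
                                       if k != "draws"},
                    "pseudo_r2": res["pseudo_r2"],
                    "rhat": {k: float(v) for k, v in res["fit"].rhat.items()},
                }
                for (outcome, label), res in ord_results.items()
            }
            (out / "ordinal_summary.json").write_text(
                json.dumps(payload, indent=2))
            manifest.outputs["ordinal_summary"] = str(out / "ordinal_summary.json")
            manifest.record("ordinal", "ok", models=list(payload))
    except Exception as e:  # noqa: BLE001
        manifest.record("ordinal", "failed", error=repr(e))

    # ---- stage: robustness (conspiracy-believer exclusion refit) -----------
    try:
        flagged = cfg.get("conspiracy_statement_id")
        if flagged is None and truth is not None:
            flagged = truth.conspiracy_statement_id
        if flagged is None:
            manifest.record("robustness", "skipped", reason="no flagged statement")
        else:
            filtered, frac = survey_io.filter_conspiracy_believers(
                responses, flagged)
            counts_f = survey_io.tabulate_counts(filtered)
            _, type1_f, _ = fit_sdt_table(counts_f)
            spec = hmeta.HierModelSpec(mcmc=hier_mcmc,
                                       **cfg.get("hier_priors", {}))
            post_f = hmeta.fit_hierarchical(counts_f, type1_f, spec)
            bf_f = hmeta.savage_dickey_bf(post_f, spec)
            payload = _hier_summary_payload(post_f, bf_f)
            payload["excluded_fraction"] = frac
            (out / "hier_summary_excl.json").write_text(
                json.dumps(payload, indent=2))
            manifest.outputs["hier_summary_excl"] = str(
                out / "hier_summary_excl.json")
            manifest.record("robustness", "ok", excluded_fraction=frac)
    except Exception as e:  # noqa: BLE001
        manifest.record("robustness", "failed", error=repr(e))

    manifest.to_json()
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest


def report(manifest: RunManifest, path=None) -> Path:
    """Render a human-readable markdown report with summary figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(manifest.out_dir)
    path = Path(path or out / "report.md")
    lines = ["# Metacognitive efficiency analysis report", ""]
    lines.append(f"Config hash `{manifest.config_hash}`, seed {manifest.seed}.")
    lines.append("")
    for stage, info in manifest.stages.items():
        lines.append(f"- **{stage}**: {info['status']}")

    if "responses" in manifest.outputs:
        df = pd.read_csv(manifest.outputs["responses"])
        table = survey_io.ResponseTable(df=df)
        fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharey=True)
        for ax, (dom, tr) in zip(
            axes.ravel(),
            [(d, t) for d in survey_io.DOMAINS for t in survey_io.TRUTHS],
        ):
            sub = table.df[(table.df["domain"] == dom) & (table.df["truth"] == tr)]
            ax.hist(sub["raw_response"], bins=np.arange(0.5, 7.5), rwidth=0.85)
            ax.set_title(f"{dom}, {tr}", fontsize=9)
            ax.set_xlabel("6-point response")
        fig.tight_layout()
        fig.savefig(out / "confidence_distributions.png", dpi=100)
        plt.close(fig)
        lines += ["", "![confidence distributions](confidence_distributions.png)"]

    if "sdt_fits" in manifest.outputs:
        sdt_df = pd.read_csv(manifest.outputs["sdt_fits"])
        lines += ["", "## Type-1 sensitivity", ""]
        for dom, grp in sdt_df.groupby("domain"):
            lines.append(f"- mean d' ({dom}): {grp['d_prime'].mean():.3f}")

    if "hier_summary" in manifest.outputs:
        hs = json.loads(Path(manifest.outputs["hier_summary"]).read_text())
        lines += ["", "## Population metacognitive efficiency (M-ratio)", ""]
        for dom, s in hs["m_ratio"].items():
            lines.append(
                f"- {dom}: {s['mean']:.3f} 95% HDI "
                f"[{s['hdi_low']:.3f}, {s['hdi_high']:.3f}]"
            )
        bfinfo = hs["bayes_factor"]
        lines.append(
            f"- domain difference BF10 = {bfinfo['bf10']:.2f} "
            f"(delta prior Normal{tuple(bfinfo['delta_prior'])})"
        )

    if "hier_summary_excl" in manifest.outputs:
        hs = json.loads(Path(manifest.outputs["hier_summary_excl"]).read_text())
        lines += ["", "## Robustness: conspiracy-endorser exclusion", ""]
        lines.append(f"- excluded fraction: {hs['excluded_fraction']:.4f}")
        for dom, s in hs["m_ratio"].items():
            lines.append(
                f"- {dom}: {s['mean']:.3f} 95% HDI "
                f"[{s['hdi_low']:.3f}, {s['hdi_high']:.3f}]"
            )

    if "ordinal_summary" in manifest.outputs:
        osum = json.loads(Path(manifest.outputs["ordinal_summary"]).read_text())
        lines += ["", "## Ordinal models (one per question)", "",
                  "| model | OR (1 SD M-ratio) | 95% HDI | pseudo-R2 |",
                  "|---|---|---|---|"]
        for name, s in osum.items():
            orr = s["odds_ratio_1sd"]
            lines.append(
                f"| {name} | {orr['mean']:.3f} | "
                f"[{orr['hdi_low']:.3f}, {orr['hdi_high']:.3f}] | "
                f"{s['pseudo_r2']:.3f} |"
            )

    path.write_text("\n".join(lines) + "\n")
    return path
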