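"""End-to-end simulated study: a 9 + 9 cohort through the full pipeline.

For every simulated participant the orchestrator runs the complete
analysis chain — training-block simulation, band-pass/epoch/artifact
pipeline, block-wise cross-validated training accuracies with binomial
chance tests, classifier-bank training, offline ERD analysis (SMR percent
power change, ERD latency, CSP quality rubric), online feedback tasks
through the six-state controller with trial-reconstruction accuracies, and
questionnaire scoring — then pools everything into the bootstrap group
statistics.  Every random stage derives its seed from the study seed, so a
result bundle is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bootstat, decode, erdlab, evalmetrics
from .controller import ControllerConfig, run_online_pipeline
from .sigproc import bandpass, epoch_training, reject_artifacts
from .synthdata import SimConfig, UserModel, generate_feedback_scenario, generate_training_recording

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResult", "run_study", "simulate_questionnaire"]

_FEEDBACK_TASKS = ("rest_move", "follow_commands", "announce_commands")


@dataclass
class StudyConfig:
    """Cohort composition, generator conditions and analysis parameters."""

    n_per_group: int = 9
    n_runs: int = 50
    seed: int = 0
    # per-subject variation of the generator conditions; stroke presets have
    # wider spread and a later mean ERD onset
    erd_depth_mean: float = 0.30
    erd_depth_sd: dict = field(default_factory=lambda: {"stroke": 0.08, "control": 0.05})
    erd_latency_sd: dict = field(default_factory=lambda: {"stroke": 0.14, "control": 0.13})
    tasks: tuple = _FEEDBACK_TASKS
    user: UserModel = field(default_factory=UserModel)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    l2_lambda: float = 1.0
    csp_shrinkage: float = 0.2
    cv_folds: int = 5
    bootstrap_B: int = 3000
    alpha: float = 0.05
    # latent questionnaire means (items discretized to the 7-point scale)
    questionnaire_means: dict = field(default_factory=lambda: {
        "SoO": 1.1, "SoA": 1.0, "ER": 1.3, "MIAB": 1.1,
        "SoO_control": -0.3, "SoA_control": -0.2,
    })

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def simulate_questionnaire(rng, means: dict):
    """Draw item-level 7-point ratings with a shared per-respondent trait.

    The common trait induces the positive inter-construct correlations seen
    in embodiment questionnaires; items add independent noise and are
    rounded and clipped to the -3..+3 scale.
    """
    trait = rng.normal(0.0, 0.9)
    ratings = {}
    for construct, items in evalmetrics.CONSTRUCT_ITEMS.items():
        base = means.get(construct, 0.0)
        loading = 0.0 if construct.endswith("_control") else 1.0
        level = base + loading * trait + rng.normal(0.0, 0.4)
        for key in items:
            ratings[key] = int(np.clip(round(level + rng.normal(0.0, 0.8)), -3, 3))
    return ratings


def _subject_conditions(cfg: StudyConfig, group: str, rng):
    depth = float(np.clip(
        rng.normal(cfg.erd_depth_mean, cfg.erd_depth_sd[group]), 0.05, 0.8))
    base = SimConfig.for_group(group)
    latency = float(np.clip(
        rng.normal(base.erd_latency, cfg.erd_latency_sd[group]), 0.15, 1.2))
    return depth, latency


def _analyze_subject(cfg: StudyConfig, group: str, subject_id: str, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    depth, latency = _subject_conditions(cfg, group, rng)

    def subseed():
        return int(rng.integers(2 ** 31))

    sim = SimConfig(n_runs=cfg.n_runs, erd_depth=depth, erd_latency=latency, seed=subseed())
    recording, events = generate_training_recording(sim)

    filtered = bandpass(recording, mode="zero_phase")
    epochs, _ = reject_artifacts(epoch_training(filtered, events))

    row = {"subject": subject_id, "group": group,
           "erd_depth_true": depth, "erd_latency_true": latency}

    # --- training accuracies ------------------------------------------------
    for name, pair in decode.CLASS_PAIRS.items():
        acc = decode.blockwise_cv_accuracy(
            epochs, pair, k=cfg.cv_folds, l2_lambda=cfg.l2_lambda,
            shrinkage=cfg.csp_shrinkage)
        n_trials = int(np.isin(epochs.labels, pair).sum())
        chance = decode.binomial_chance_level(n_trials, alpha=cfg.alpha)
        row[f"train_acc_{name}"] = acc
        row[f"train_above_chance_{name}"] = acc >= chance
    row["train_acc_mean"] = float(np.mean([row[f"train_acc_{n}"] for n in decode.CLASS_PAIRS]))

    bank = decode.train_bank(epochs, l2_lambda=cfg.l2_lambda, shrinkage=cfg.csp_shrinkage)

    # --- offline ERD analysis ----------------------------------------------
    traces_pool = []
    for cls, model_name in (("flexion", "Y_OF"), ("extension", "Y_CE")):
        model = bank.csp_models[model_name]
        comp = erdlab.choose_component(model, epochs, decode.CLASS_PAIRS[model_name])
        segs, labels, times = erdlab.csp_component_segments(
            recording, events, model.filters_[:, comp])
        cls_segs = segs[labels == cls]
        power, t_crop, freqs = erdlab.morlet_tf(cls_segs, sim.fs, times=times)
        tf = erdlab.percent_power_change(power, t_crop, freqs)
        row[f"smr_change_{cls}"] = erdlab.mean_smr_change(tf)
        traces_pool.append(erdlab.band_power_traces(power, t_crop, freqs))
    row["erd_latency_s"] = erdlab.erd_latency(np.vstack(traces_pool), t_crop)

    quality = erdlab.csp_quality_score(bank.csp_models["Y_OF"], bank.csp_models["Y_CE"], epochs)
    row["csp_quality"] = quality.total
    row["csp_plausible"] = quality.plausible

    # --- feedback tasks ------------------------------------------------------
    accs = []
    for task in cfg.tasks:
        scenario = generate_feedback_scenario(
            dataclasses.replace(sim, seed=subseed()), cfg.user, task)
        trace = run_online_pipeline(scenario.recording, bank, cfg.controller)
        if task == "rest_move":
            ledger = evalmetrics.rest_move_ledger(trace, scenario.events)
            move_n, rest_n = evalmetrics.rest_move_counts(trace, scenario.events)
            row["movements_move_phase"] = float(move_n.mean())
            row["movements_rest_phase"] = float(rest_n.mean())
        else:
            commands = [e for e in scenario.events if e.label.startswith("command_")]
            from .io import EventMarker
            movements = [EventMarker(t, lab) for t, lab in trace.movements]
            ledger = evalmetrics.reconstruct_trials(
                commands, movements, scenario.recording.duration)
        acc = evalmetrics.feedback_accuracy(ledger) if len(ledger) else float("nan")
        row[f"feedback_acc_{task}"] = acc
        n_trials = len(ledger)
        if n_trials:
            _, above = decode.accuracy_ci_above_chance(acc / 100.0, n_trials, alpha=cfg.alpha)
            row[f"feedback_above_chance_{task}"] = above
        accs.append(acc)
    row["feedback_acc_mean"] = float(np.nanmean(accs)) if accs else float("nan")

    # --- questionnaires (training and feedback block) ------------------------
    for block in ("training", "feedback"):
        scores = evalmetrics.score_questionnaire(
            simulate_questionnaire(rng, cfg.questionnaire_means))
        for s in scores:
            row[f"q_{s.construct}_{block}"] = s.mean
            if not s.construct.endswith("_control"):
                row[f"q_{s.construct}_{block}_induced"] = s.induced
    return row


def _anova_table(df, value_cols, factor_name):
    """Long-format 2x2 mixed design from two per-subject columns."""
    rows = []
    for _, r in df.iterrows():
        for level, col in value_cols.items():
            rows.append({"subject": r["subject"], "group": r["group"],
                         "condition": level, "value": r[col]})
    return pd.DataFrame(rows)


def _result_to_dict(res: bootstat.BootstrapResult):
    out = {"observed": res.observed, "p": res.p, "B": res.B}
    if res.ci is not None:
        out["ci"] = list(res.ci)
    out.update(res.extra if res.extra else {})
    return out


def _run_statistics(df: pd.DataFrame, cfg: StudyConfig, rng) -> dict:
    B = cfg.bootstrap_B

    def bseed():
        return int(rng.integers(2 ** 31))

    stats: dict = {"anova": {}, "ttest": {}, "correlation": {}}

    anovas = {
        "smr_change_group_x_class": {"flexion": "smr_change_flexion",
                                     "extension": "smr_change_extension"},
        "movements_group_x_phase": {"move": "movements_move_phase",
                                    "rest": "movements_rest_phase"},
    }
    for construct in ("SoO", "SoA", "ER", "MIAB"):
        anovas[f"q_{construct}_group_x_block"] = {
            "training": f"q_{construct}_training", "feedback": f"q_{construct}_feedback"}
    for name, cols in anovas.items():
        if not all(c in df.columns for c in cols.values()):
            continue
        table = _anova_table(df, cols, name)
        if table["value"].isna().any():
            continue
        res = bootstat.bootstrap_mixed_anova(table, B=B, seed=bseed())
        stats["anova"][name] = {k: _result_to_dict(v) for k, v in res.items()}

    groups = sorted(df["group"].unique())
    if len(groups) == 2:
        g0, g1 = (df[df["group"] == g] for g in groups)
        for name, col in (("erd_latency", "erd_latency_s"),
                          ("csp_quality", "csp_quality"),
                          ("feedback_accuracy", "feedback_acc_mean"),
                          ("training_accuracy", "train_acc_mean")):
            x, y = g0[col].dropna(), g1[col].dropna()
            if len(x) >= 2 and len(y) >= 2 and np.var(np.r_[x, y]) > 0:
                stats["ttest"][name] = _result_to_dict(
                    bootstat.bootstrap_ttest(x, y, B=B, seed=bseed()))

    # pooled-block construct correlations
    constructs = ("SoO", "SoA", "ER", "MIAB")
    pooled = {
        c: np.r_[df[f"q_{c}_training"].to_numpy(), df[f"q_{c}_feedback"].to_numpy()]
        for c in constructs
        if f"q_{c}_training" in df.columns and f"q_{c}_feedback" in df.columns
    }
    corr_ps = {}
    for i, a in enumerate(constructs):
        for b in constructs[i + 1:]:
            if a in pooled and b in pooled and np.std(pooled[a]) > 0 and np.std(pooled[b]) > 0:
                res = bootstat.bootstrap_correlation(pooled[a], pooled[b], B=B, seed=bseed())
                stats["correlation"][f"{a}_vs_{b}"] = _result_to_dict(res)
                corr_ps[f"{a}_vs_{b}"] = res.p
    if corr_ps:
        reject, p_adj = bootstat.holm_correction(list(corr_ps.values()), alpha=cfg.alpha)
        for (name, _), rej, pa in zip(corr_ps.items(), reject, p_adj):
            stats["correlation"][name]["p_holm"] = float(pa)
            stats["correlation"][name]["significant_holm"] = bool(rej)
    return stats


@dataclass
class StudyResult:
    """Per-subject metrics plus the pooled statistics report."""

    subjects: pd.DataFrame
    stats: dict
    config: StudyConfig
    seed: int

    def write_bundle(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"seed": self.seed, "config_hash": self.config.config_hash(),
                "config": dataclasses.asdict(self.config), "n_subjects": len(self.subjects)}
        self.subjects.to_csv(out / "subjects.csv", index=False)
        with open(out / "stats.json", "w") as fh:
            json.dump({"meta": meta, "stats": self.stats}, fh, indent=1, default=str)
        with open(out / "report.txt", "w") as fh:
            fh.write(self.text_report())
        return out

    def text_report(self) -> str:
        df = self.subjects
        lines = [
            f"Simulated self-paced neurofeedback study (seed={self.seed}, "
            f"config {self.config.config_hash()})",
            f"subjects: {len(df)} ({dict(df['group'].value_counts())})",
            "",
        ]
        for group, sub in df.groupby("group"):
            lines.append(f"[{group}]")
            lines.append(f"  SMR change flexion/extension (%): "
                         f"{sub['smr_change_flexion'].mean():.1f} / "
                         f"{sub['smr_change_extension'].mean():.1f}")
            lines.append(f"  ERD latency (ms): {1e3 * sub['erd_latency_s'].mean():.0f}")
            lines.append(f"  CSP quality (0-12): {sub['csp_quality'].mean():.1f}")
            lines.append(f"  training accuracy: {100 * sub['train_acc_mean'].mean():.1f}%")
            if "feedback_acc_mean" in sub:
                lines.append(f"  feedback accuracy: {sub['feedback_acc_mean'].mean():.1f}%")
            lines.append("")
        for family, tests in self.stats.items():
            for name, res in tests.items():
                if family == "anova":
                    for effect, r in res.items():
                        lines.append(f"ANOVA {name} [{effect}]: F={r['observed']:.2f} p={r['p']:.3f}")
                else:
                    lines.append(f"{family} {name}: stat={res['observed']:.2f} p={res['p']:.3f}")
        return "\n".join(lines) + "\n"


def run_study(config: StudyConfig = None) -> StudyResult:
    """Run the full simulated study defined by ``config``."""
    cfg = config or StudyConfig()
    master = np.random.default_rng(cfg.seed)
    rows = []
    for group in ("stroke", "control"):
        for i in range(cfg.n_per_group):
            sid = f"{group[0]}{i + 1:02d}"
            seed = int(master.integers(2 ** 31))
            logger.info("analyzing simulated subject %s", sid)
            rows.append(_analyze_subject(cfg, group, sid, seed))
    df = pd.DataFrame(rows)
    stats = _run_statistics(df, cfg, master)
    return StudyResult(subjects=df, stats=stats, config=cfg, seed=cfg.seed)
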