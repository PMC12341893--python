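"""End-to-end orchestration of the synthetic study.

``run_study`` chains every stage — word-set synthesis, triad and pair
designs, cohort simulation, QC, pooled and per-patient BMDS fits, dimension
regressions, spatial-randomness distributions with the group KS comparison,
relative scales with Kendall agreement, single-case tests and Procrustes
mapping — and writes each stage's CSV/JSON artefacts to an output
directory.  Everything is deterministic given the study seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bmds, design, interpret, qc, randomness, scales, simulate, stimuli

log = logging.getLogger("semspace")


@dataclass
class StudyConfig:
    """Top-level configuration of a synthetic study run."""

    seed: int = 0
    n_control: int = 77
    n_sv: int = 10
    n_per_class: int = 8
    triad_trials: int = 192
    triad_duplicates: int = 24
    n_blocks: int = 16
    n_patient_fits: int | None = None     # None = all sv participants
    bmds: bmds.BmdsConfig = field(default_factory=bmds.BmdsConfig)
    n_random: int = 10_000
    out_dir: str = "semspace_out"

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        bm = raw.pop("bmds", {})
        return cls(bmds=bmds.BmdsConfig(**bm), **raw)

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def reduced_study_config(**overrides) -> StudyConfig:
    """A smoke-test-scale study (few participants, short chains)."""
    defaults = dict(
        n_control=5,
        n_sv=2,
        bmds=bmds.reduced_config(warmup=100, kept=200, n_retain=20),
        n_random=200,
    )
    defaults.update(overrides)
    return StudyConfig(**defaults)


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))


def run_study(cfg: StudyConfig) -> dict:
    """Run the full synthetic study and write all artefacts.

    Returns a bundle dict with the in-memory results of every stage.  On a
    stage failure the artefacts written so far remain in ``cfg.out_dir`` and
    the raised error names the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    digest = cfg.digest()
    bundle: dict = {"config_digest": digest}
    run_log: list[dict] = []

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s", name)

        def done():
            run_log.append({"stage": name, "seconds": time.perf_counter() - t0})

        return done

    try:
        done = stage("words")
        ws = stimuli.synthesize_word_set(
            seed=int(rng.integers(2**31)), n_per_class=cfg.n_per_class
        )
        stimuli.write_word_norms(ws, out / "word_norms.csv")
        matching = stimuli.check_matching(ws)
        matching.to_csv(out / "word_matching.csv")
        bundle["word_set"] = ws
        done()

        done = stage("designs")
        td = design.build_triad_design(
            ws,
            seed=int(rng.integers(2**31)),
            n_presented=cfg.triad_trials,
            n_duplicates=cfg.triad_duplicates,
        )
        pdn = design.build_pair_design(
            ws, seed=int(rng.integers(2**31)), n_blocks=cfg.n_blocks
        )
        td.to_frame().to_csv(out / "triad_design.csv", index=False)
        pdn.to_frame().to_csv(out / "pair_design.csv", index=False)
        bundle["triad_design"], bundle["pair_design"] = td, pdn
        done()

        done = stage("simulate")
        gc = simulate.GeneratorConfig(n_control=cfg.n_control, n_sv=cfg.n_sv)
        responses, truth = simulate.simulate_cohort(
            ws, td, pdn, gc, seed=int(rng.integers(2**31))
        )
        responses.to_csv(out / "responses.csv", index=False)
        _write_json(
            {
                "W": {g: truth["W"][g] for g in truth["W"]},
                "profiles": {
                    p: asdict(pr) for p, pr in truth["profiles"].items()
                },
                "configs": {
                    g: truth["configs"][g].coords for g in truth["configs"]
                },
            },
            out / "ground_truth.json",
        )
        bundle["responses"], bundle["truth"] = responses, truth
        done()

        done = stage("qc")
        qc_rows = []
        for pid, sub in responses.groupby("participant_id"):
            tri = sub[sub["task"] == "triad"]
            qc_rows.append((pid, qc.triad_consistency(tri, td)))
            for task in ("concreteness", "valence"):
                pr = sub[sub["task"].isin(["pair_conc", "pair_val"])]
                qc_rows.append((pid, qc.pair_consistency(pr, pdn, task)))
        qc_df = qc.consistency_report(qc_rows)
        qc_df.to_csv(out / "qc_consistency.csv", index=False)
        bundle["qc"] = qc_df
        done()

        done = stage("bmds_fits")
        tri_all = responses[responses["task"] == "triad"]
        fits: dict[str, bmds.PosteriorSamples] = {}
        for group, label in (("control_like", "HC"), ("sv_like", "SV")):
            sub = tri_all[tri_all["group"] == group]
            ps = bmds.fit_bmds(
                sub, ws.word_ids, cfg.bmds, seed=int(rng.integers(2**31))
            )
            ps = bmds.align_samples(
                ps, reference=truth["configs"][group].coords
            )
            fits[label] = ps
            bmds.samples_to_frame(ps).to_csv(
                out / f"posterior_{label}.csv", index=False
            )
            bmds.deltas_to_frame(ps).to_csv(
                out / f"posterior_{label}_deltas.csv", index=False
            )
            _write_json(ps.diagnostics, out / f"diagnostics_{label}.json")
        bundle["fits"] = fits
        done()

        done = stage("patient_fits")
        sv_ids = sorted(tri_all[tri_all["group"] == "sv_like"]["participant_id"].unique())
        if cfg.n_patient_fits is not None:
            sv_ids = sv_ids[: cfg.n_patient_fits]
        patient_reports = []
        for pid in sv_ids:
            sub = tri_all[tri_all["participant_id"] == pid]
            mean_res, dists = interpret.interpret_patient(
                sub, ws, cfg.bmds, seed=int(rng.integers(2**31)),
                reference=truth["configs"]["sv_like"].coords,
            )
            patient_reports.append(interpret.report_frame(pid, mean_res, dists))
        if patient_reports:
            pd.concat(patient_reports, ignore_index=True).to_csv(
                out / "patient_regressions.csv", index=False
            )
        bundle["patient_reports"] = patient_reports
        done()

        done = stage("interpret")
        reports = []
        for label, ps in fits.items():
            mean_res, dists = interpret.interpret_fit(ps, ws)
            reports.append(interpret.report_frame(label, mean_res, dists))
            bundle[f"interpret_{label}"] = (mean_res, dists)
        pd.concat(reports, ignore_index=True).to_csv(
            out / "group_regressions.csv", index=False
        )
        done()

        done = stage("randomness")
        r_results = {}
        for label, ps in fits.items():
            rr = randomness.randomness_over_samples(
                ps, n_random=cfg.n_random, seed=int(rng.integers(2**31))
            )
            r_results[label] = rr
            pd.DataFrame(
                {"sample_index": range(len(rr.R)), "R": rr.R}
            ).to_csv(out / f"randomness_{label}.csv", index=False)
        D, p = randomness.compare_R_distributions(r_results["HC"], r_results["SV"])
        _write_json(
            {
                "HC": {"mean": r_results["HC"].mean, "sd": r_results["HC"].sd},
                "SV": {"mean": r_results["SV"].mean, "sd": r_results["SV"].sd},
                "ks_D": D,
                "ks_p": p,
                "n_random": cfg.n_random,
            },
            out / "randomness_summary.json",
        )
        bundle["randomness"] = r_results
        bundle["randomness_ks"] = (D, p)
        done()

        done = stage("scales")
        pair_all = responses[responses["task"].isin(["pair_conc", "pair_val"])]
        scale_rows, kendall_rows, ss_rows = [], [], []
        per_participant: dict[str, dict] = {}
        for pid, sub in pair_all.groupby("participant_id"):
            group = sub["group"].iloc[0]
            entry: dict = {"group": group}
            for task in ("concreteness", "valence"):
                rs = scales.build_relative_scale(sub, pdn, task)
                tau, tau_p = scales.kendall_vs_ratings(rs, ws)
                entry[f"scale_{task}"] = rs
                entry[f"tau_{task}"] = tau
                scale_rows.append(rs.to_frame().assign(participant_id=pid))
                kendall_rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "task": task,
                        "tau": tau,
                        "p": tau_p,
                    }
                )
            pr = scales.combine_and_procrustes(
                entry["scale_valence"], entry["scale_concreteness"], ws
            )
            entry["procrustes"] = pr
            ss_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "ss_error": pr.ss_error,
                }
            )
            per_participant[pid] = entry
        pd.concat(scale_rows, ignore_index=True).to_csv(
            out / "relative_scales.csv", index=False
        )
        kendall_df = pd.DataFrame(kendall_rows)
        kendall_df.to_csv(out / "kendall.csv", index=False)
        ss_df = pd.DataFrame(ss_rows)
        ss_df.to_csv(out / "procrustes_ss.csv", index=False)

        # single-case comparisons of each sv-like participant against controls
        case_rows = []
        hc_mask = kendall_df["group"] == "control_like"
        for task in ("concreteness", "valence"):
            hc_tau = kendall_df[hc_mask & (kendall_df["task"] == task)]["tau"]
            for pid, entry in per_participant.items():
                if entry["group"] != "sv_like":
                    continue
                sc = scales.crawford_howell(entry[f"tau_{task}"], hc_tau)
                case_rows.append(
                    {
                        "patient_id": pid,
                        "measure": f"kendall_{task}",
                        "case_value": sc.case_value,
                        "t": sc.t,
                        "df": sc.df,
                        "p": sc.p,
                    }
                )
        hc_ss = ss_df[ss_df["group"] == "control_like"]["ss_error"]
        anova_rows = []
        for pid, entry in per_participant.items():
            if entry["group"] != "sv_like":
                continue
            sc = scales.crawford_howell(entry["procrustes"].ss_error, hc_ss)
            case_rows.append(
                {
                    "patient_id": pid,
                    "measure": "procrustes_ss",
                    "case_value": sc.case_value,
                    "t": sc.t,
                    "df": sc.df,
                    "p": sc.p,
                }
            )
            if sc.p < 0.05 and sc.t > 0:
                F, p_anova = scales.stimulus_error_anova(entry["procrustes"], ws)
                anova_rows.append(
                    {"patient_id": pid, "F": F, "p": p_anova}
                )
        pd.DataFrame(case_rows).to_csv(out / "single_case.csv", index=False)
        if anova_rows:
            pd.DataFrame(anova_rows).to_csv(
                out / "stimulus_error_anova.csv", index=False
            )
        bundle["scales"] = per_participant
        bundle["single_case"] = pd.DataFrame(case_rows)
        done()
    except Exception as e:
        failed = run_log[-1]["stage"] if run_log else "setup"
        raise RuntimeError(
            f"study failed after stage {failed!r}: {e}"
        ) from e

    _write_json(
        {"config": asdict(cfg), "digest": digest, "stages": run_log},
        out / "run_log.json",
    )
    bundle["run_log"] = run_log
    return bundle
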