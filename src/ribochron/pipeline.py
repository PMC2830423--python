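"""End-to-end pipeline orchestration.

``run_pipeline`` composes the stages — REO matrices from rule sets,
usage-delta profiles, raw/background/residual RMSD matrices, the walk
landscape, the extracted chronology alignment, and the congruence report
— writing every artifact plus a manifest recording seeds, modes and
versions, so a run directory is reproducible bit for bit from its config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chronology import (
    background_matrix,
    randomized_residuals,
    residual_matrix,
    rmsd_matrix,
    structure_test,
)
from .congruence import congruence_table
from .pathwalk import extract_alignment, path_landscape, random_walks
from .pleo import CapacityError, count_pleos, reo_matrix, sample_pleos
from .rules import AssemblyRuleSet, load_ruleset
from .usage import UsageTable, delta_profile

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "subunit_chronology"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    lsu_rules: str
    ssu_rules: str
    lsu_usage: str
    ssu_usage: str
    out_dir: str
    pleo_mode: str = "auto"  # exact | sample | auto (exact when countable)
    pleo_n: int = 100_000
    pleo_exact_cap: int = 10**8
    delta_variant: str = "rate_difference"
    background_reps: int = 10_000
    n_randomized: int = 100
    n_walks: int = 1_000_000
    q_levels: tuple[float, ...] = (0.05, 0.01)
    alignment_method: str = "best_walk"
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["q_levels"] = list(self.q_levels)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["q_levels"] = tuple(d.get("q_levels", (0.05, 0.01)))
        return cls(**d)


def subunit_chronology(
    rs: AssemblyRuleSet,
    mode: str = "auto",
    n: int = 100_000,
    seed: int = 0,
    exact_cap: int = 10**8,
):
    """REO matrix for one subunit, with excluded proteins removed.

    ``mode="auto"`` uses the exact subset-DP probabilities when the
    extension count is below ``exact_cap`` and falls back to uniform
    sampling of ``n`` orders otherwise — the same split applied to the
    two real subunit maps (exhaustive LSU, sampled SSU).
    """
    if mode == "auto":
        mode = "exact" if count_pleos(rs) <= exact_cap else "sample"
    if mode == "exact":
        return reo_matrix(rs, exclude=rs.usage_excluded)
    if mode == "sample":
        orders = sample_pleos(rs, n, seed, method="uniform")
        return reo_matrix(
            orders,
            exclude=rs.usage_excluded,
            provenance={"method": "uniform", "n": n, "seed": seed},
        )
    raise ValueError(f"unknown PLEO mode {mode!r}")


def _stage(name: str):
    def wrap(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage label
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write artifacts plus ``manifest.json``.

    Returns the run directory. On stage failure, partial outputs are
    retained alongside a ``FAILED`` marker naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    rng = np.random.SeedSequence(cfg.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("pleo_lsu", "pleo_ssu", "background", "randomized", "walks"),
            rng.spawn(5),
        )
    }

    def save(name: str, writer) -> None:
        writer(out / name)
        artifacts.append(name)

    try:
        rsL = _stage("rules")(load_ruleset, cfg.lsu_rules)
        rsS = _stage("rules")(load_ruleset, cfg.ssu_rules)
        tL = _stage("usage")(UsageTable.from_tsv, cfg.lsu_usage, "LSU")
        tS = _stage("usage")(UsageTable.from_tsv, cfg.ssu_usage, "SSU")

        reoL = _stage("reo")(
            subunit_chronology, rsL, cfg.pleo_mode, cfg.pleo_n, seeds["pleo_lsu"], cfg.pleo_exact_cap
        )
        reoS = _stage("reo")(
            subunit_chronology, rsS, cfg.pleo_mode, cfg.pleo_n, seeds["pleo_ssu"], cfg.pleo_exact_cap
        )
        save("reo_lsu.tsv", reoL.to_tsv)
        save("reo_ssu.tsv", reoS.to_tsv)

        dL = _stage("delta")(delta_profile, reoL, tL, cfg.delta_variant)
        dS = _stage("delta")(delta_profile, reoS, tS, cfg.delta_variant)
        save("delta_lsu.tsv", dL.to_tsv)
        save("delta_ssu.tsv", dS.to_tsv)

        raw = _stage("rmsd")(rmsd_matrix, dL, dS)
        bg = _stage("background")(
            background_matrix, tL, tS, reoL, reoS, cfg.background_reps,
            seeds["background"], cfg.delta_variant,
        )
        res = _stage("residual")(residual_matrix, raw, bg)
        save("rmsd_raw.tsv", raw.to_tsv)
        save("rmsd_background.tsv", bg.to_tsv)
        save("rmsd_residual.tsv", res.to_tsv)

        rand = _stage("structure")(
            randomized_residuals, tL, tS, reoL, reoS, bg, cfg.n_randomized,
            seeds["randomized"], cfg.delta_variant,
        )
        report = _stage("structure")(structure_test, res, rand)
        (out / "structure_test.json").write_text(json.dumps(report, indent=1))
        artifacts.append("structure_test.json")

        for q in cfg.q_levels:
            land = _stage("landscape")(path_landscape, res, cfg.n_walks, seeds["walks"], q)
            save(f"landscape_q{q:g}.tsv", land.to_tsv)
        if cfg.alignment_method == "best_walk":
            aln = _stage("align")(
                extract_alignment, random_walks(res, cfg.n_walks, seeds["walks"])
            )
        elif cfg.alignment_method == "ridge":
            land = path_landscape(res, cfg.n_walks, seeds["walks"], cfg.q_levels[0])
            aln = _stage("align")(extract_alignment, land, "ridge")
        else:
            raise PipelineError(f"stage 'align' failed: unknown method {cfg.alignment_method!r}")
        save("alignment.tsv", aln.to_tsv)

        rep = _stage("congruence")(congruence_table, dL, dS, aln)
        save("congruence.tsv", rep.to_tsv)

        manifest = {
            "version": __version__,
            "config": json.loads(cfg.to_json()),
            "derived_seeds": seeds,
            "artifacts": artifacts,
            "grand_convergence": {"z_v_lsu_ave": rep.z_v_lsu_ave, "z_v_ssu_ave": rep.z_v_ssu_ave},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except PipelineError as exc:
        (out / "FAILED").write_text(str(exc) + "\n")
        raise
    return out
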