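"""End-to-end orchestration: structures in, statistical potentials out.

Stage order mirrors the derivation: load -> globularity filter -> fragment
collection per level -> Maxwell fits, plateau and thermal exponent -> CV
bandwidths and the w = a*n^s model -> per-m densities -> per-m potentials ->
plateau average V* (70-90) and broad average V-bar (30-90) -> minima and
short-range power law -> optional sequence-dependent pass.  Every stage
persists its intermediates under the run directory, and a failed stage
aborts naming itself while keeping what finished.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dataset_filter, fragments, kde, maxwell, potential
from .errors import FlorypotError, PipelineStageError
from .io_structures import CoarseGrainLevel, load_directory, radius_of_gyration

logger = logging.getLogger("florypot.pipeline")


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str = "florypot_run"
    levels: tuple[str, ...] = ("CA",)
    m_collect: tuple[int, int] = (30, 90)
    m_plateau: tuple[int, int] = (70, 90)
    m_broad: tuple[int, int] = (30, 90)
    globularity_k: float = 3.0
    cv_m_list: tuple[int, ...] = (42, 48, 60, 64, 66, 72, 78, 84, 92)
    n_folds: int = 5
    seed: int = 0
    grid_min: float = 0.0
    grid_max: float = 30.0
    grid_step: float = 0.1
    min_count_seqdep: int = 50
    seqdep_pairs: tuple[tuple[str, str], ...] = ()
    w_grid: tuple[float, ...] | None = None

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return np.round(np.linspace(self.grid_min, self.grid_max, n), 10)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "seqdep_pairs" in d:
            d["seqdep_pairs"] = tuple(tuple(p) for p in d["seqdep_pairs"])
        for key in ("levels", "m_collect", "m_plateau", "m_broad", "cv_m_list"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("w_grid") is not None:
            d["w_grid"] = tuple(d["w_grid"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except FlorypotError as exc:
                raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full derivation; returns the summary (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.json")
    summary: dict = {"seed": config.seed}

    # --- load -------------------------------------------------------------
    try:
        structures = load_directory(config.input_dir)
    except FlorypotError as exc:
        raise PipelineStageError(f"stage 'load' failed: {exc}") from exc
    if not structures:
        raise PipelineStageError(
            f"stage 'load' failed: no parsable structure in {config.input_dir}"
        )
    chains, chain_ids = [], []
    for st in structures:
        for k, ch in enumerate(st.chains):
            if ch.N >= 2:
                chains.append(ch)
                chain_ids.append(f"{st.id}:{k}")
    logger.info("loaded %d chains from %d structures", len(chains), len(structures))

    # --- globularity filter ----------------------------------------------
    points, ids = [], []
    for ch, cid in zip(chains, chain_ids):
        try:
            points.append((ch.N, radius_of_gyration(ch)))
            ids.append(cid)
        except FlorypotError:
            logger.warning("chain %s skipped in globularity stage", cid)
    try:
        gfit = dataset_filter.fit_globularity(points, ids=ids, k=config.globularity_k)
    except FlorypotError as exc:
        raise PipelineStageError(f"stage 'globularity' failed: {exc}") from exc
    gfit.write_report(out / "globularity.tsv")
    retained = set(gfit.retained_ids)
    kept = [(ch, cid) for ch, cid in zip(chains, chain_ids) if cid in retained]
    summary["globularity"] = {
        "a": gfit.a,
        "residual_sd": gfit.residual_sd,
        "n_retained": len(gfit.retained_ids),
        "n_discarded": len(gfit.discarded_ids),
    }
    logger.info("globularity: kept %d, discarded %d", len(gfit.retained_ids),
                len(gfit.discarded_ids))

    grid = config.grid()
    summary["levels"] = {}
    for level_name in config.levels:
        level = CoarseGrainLevel(level_name)
        lv: dict = {}
        # --- fragment collection ------------------------------------------
        try:
            sets = fragments.collect_distances(
                [ch for ch, _ in kept],
                config.m_collect,
                level,
                structure_ids=[cid for _, cid in kept],
            )
        except FlorypotError as exc:
            raise PipelineStageError(
                f"stage 'fragments/{level.value}' failed: {exc}"
            ) from exc
        fragments.fragment_sets_to_tsv(sets, out / f"fragments_{level.value}.tsv")
        lv["n_by_m"] = {str(m): sets[m].n for m in sorted(sets)}
        lv["skipped_by_m"] = {
            str(m): sets[m].n_skipped for m in sorted(sets) if sets[m].n_skipped
        }

        # --- Maxwell fits, plateau, thermal exponent ----------------------
        try:
            fits = [
                maxwell.fit_kuhn_length(sets[m]) for m in sorted(sets) if sets[m].n >= 2
            ]
            maxwell.fits_to_tsv(fits, out / f"kuhn_fits_{level.value}.tsv")
            plateau = maxwell.plateau_kuhn_length(fits, config.m_plateau)
            lv["b_star"] = plateau.b_star
            lv["sigma_b_star"] = plateau.sigma_b_star
        except FlorypotError as exc:
            raise PipelineStageError(
                f"stage 'maxwell/{level.value}' failed: {exc}"
            ) from exc
        mean_R = {
            m: float(np.mean(sets[m].distances)) for m in sorted(sets) if sets[m].n
        }
        try:
            scaling = maxwell.scaling_exponent(mean_R, config.m_plateau)
            lv["nu"] = scaling.nu
            lv["nu_stderr"] = scaling.nu_stderr
        except FlorypotError as exc:
            raise PipelineStageError(
                f"stage 'scaling/{level.value}' failed: {exc}"
            ) from exc

        # --- CV bandwidths + scaling model --------------------------------
        cv_points = []
        for m in config.cv_m_list:
            fs = sets.get(m)
            if fs is None or fs.n < 2 * config.n_folds:
                logger.warning("CV separation m=%d unavailable at %s", m, level.value)
                continue
            w_cv = kde.cross_validate_bandwidth(
                fs, n_folds=config.n_folds, w_grid=config.w_grid, seed=config.seed
            )
            cv_points.append((fs.n, w_cv, m))
        try:
            ns = [n for n, _, _ in cv_points]
            if len(set(ns)) >= 2 and max(ns) / min(ns) >= 1.5:
                bw_model = kde.fit_bandwidth_scaling([(n, w) for n, w, _ in cv_points])
            elif cv_points:
                # the power law is unidentifiable over a narrow n range:
                # use the mean cross-validated bandwidth instead
                bw_model = kde.BandwidthModel(
                    a_bw=float(np.mean([w for _, w, _ in cv_points])), s_bw=0.0
                )
                logger.warning(
                    "CV sample sizes span < 1.5x; constant bandwidth model"
                )
            else:
                raise PipelineStageError(
                    f"stage 'bandwidth/{level.value}' failed: no CV separation usable"
                )
        except FlorypotError as exc:
            raise PipelineStageError(
                f"stage 'bandwidth/{level.value}' failed: {exc}"
            ) from exc
        import pandas as pd

        pd.DataFrame(
            [(m, n, w) for n, w, m in cv_points], columns=["m", "n", "w_cv"]
        ).to_csv(out / f"bandwidths_{level.value}.tsv", sep="\t", index=False)
        lv["bandwidth_model"] = {"a": bw_model.a_bw, "s": bw_model.s_bw}

        # --- potentials ----------------------------------------------------
        try:
            sp_flory = potential.derive_potentials(
                sets, bw_model, config.m_plateau, kind="flory_70_90", grid=grid
            )
            sp_broad = potential.derive_potentials(
                sets, bw_model, config.m_broad, kind="broad_30_90", grid=grid
            )
        except FlorypotError as exc:
            raise PipelineStageError(
                f"stage 'potential/{level.value}' failed: {exc}"
            ) from exc
        minima = potential.find_minima(sp_flory)
        try:
            repulsion = potential.fit_repulsive_power_law(sp_broad)
            lv["repulsion_exponent"] = repulsion.exponent
            lv["repulsion_stderr"] = repulsion.exponent_stderr
        except FlorypotError as exc:
            repulsion = None
            logger.warning("power-law fit failed at %s: %s", level.value, exc)
        potential.potential_to_tsv(
            sp_flory,
            out / f"potential_flory_{level.value}.tsv",
            sidecar=out / f"potential_flory_{level.value}.json",
            minima=minima,
            repulsion=None,
        )
        potential.potential_to_tsv(
            sp_broad,
            out / f"potential_broad_{level.value}.tsv",
            sidecar=out / f"potential_broad_{level.value}.json",
            minima=None,
            repulsion=repulsion,
        )
        lv["minima"] = [list(x) for x in minima.minima]

        # --- optional sequence-dependent pass ------------------------------
        seqdep: dict = {}
        for aa1, aa2 in config.seqdep_pairs:
            restricted = {
                m: fragments.filter_by_terminal_types(sets[m], aa1, aa2)
                for m in sets
            }
            try:
                sp_pair = potential.derive_sequence_dependent(
                    restricted,
                    bw_model,
                    (aa1, aa2),
                    m_range=config.m_broad,
                    min_count_per_m=config.min_count_seqdep,
                    grid=grid,
                )
            except FlorypotError as exc:
                logger.warning("seqdep %s-%s skipped: %s", aa1, aa2, exc)
                continue
            tag = f"{aa1}_{aa2}_{level.value}"
            potential.potential_to_tsv(
                sp_pair,
                out / f"potential_seqdep_{tag}.tsv",
                sidecar=out / f"potential_seqdep_{tag}.json",
            )
            seqdep[f"{aa1}-{aa2}"] = {
                "n_m_used": len(sp_pair.per_m_curves),
            }
        if seqdep:
            lv["seqdep"] = seqdep
        summary["levels"][level.value] = lv

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
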