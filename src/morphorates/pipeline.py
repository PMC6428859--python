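"""End-to-end workflow: outlines -> coefficients -> comparative statistics.

`run_full_pipeline` wires the stages in the order the analysis runs:

1. read specimen metadata, outline files and the phylogeny;
2. elliptic Fourier analysis and size normalization per specimen;
3. species mean shapes per trait block (tree tip order);
4. phylogenetic signal (K_mult) per block;
5. evolutionary rate comparison across blocks, with bootstrap CIs;
6. phylogenetic two-block PLS for every block pair;
7. specimen-level statistics: shape PCA, repeatability of PC scores,
   PC ~ species (+ sex) + size models, and the variance-ratio test on
   species-mean PC1 of the first two blocks;
8. ancestral states and traitgram coordinates on species-mean PC1 of
   the first two blocks.

Every stage writes a CSV into the output directory; reruns with the
same configuration and seed are byte-identical.  Randomness is governed
by a single seed from which per-stage streams are derived
deterministically.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .efa import (
    assemble_block,
    compute_efa,
    normalize_coefficients,
    shape_pca,
    species_mean_shapes,
)
from .errors import ConfigError, DataError, StageError
from .integration import phylo_pls
from .io_formats import (
    read_newick,
    read_specimen_table,
    read_tps_outlines,
    write_table,
)
from .rates import bootstrap_sigma2_ci, compare_rates
from .signal import kmult_test
from .specimen_stats import repeatability, shape_effects_model, variance_ratio_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    specimens: Path
    tree: Path
    out_dir: Path
    harmonics: int = 20
    normalization: str = "size"
    blocks: tuple[str, ...] | None = None  # default: every trait in the metadata
    n_perm: int = 1000
    n_sim: int = 1000
    n_boot: int = 1000
    pls_perm: int = 10000
    seed: int = 1
    flip_y: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("harmonics", "n_perm", "n_sim", "n_boot", "pls_perm"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.normalization not in ("size", "full"):
            raise ConfigError("normalization must be 'size' or 'full'")
        for path_attr in ("specimens", "tree"):
            path = Path(getattr(self, path_attr))
            if not path.exists():
                raise ConfigError(f"{path_attr} path does not exist: {path}")


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    """One deterministic 31-bit child seed per named stage."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and write result tables under ``config.out_dir``.

    Returns a bundle (dict) with the in-memory results keyed by stage.
    Any stage failure raises :class:`StageError` carrying the stage name.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrap

    meta = stage("read_metadata")(lambda: read_specimen_table(config.specimens))
    tree = stage("read_tree")(lambda: read_newick(config.tree))
    blocks = (
        list(config.blocks)
        if config.blocks
        else sorted(meta["trait"].unique().tolist())
    )
    missing = set(blocks) - set(meta["trait"].unique())
    if missing:
        raise StageError(
            "read_metadata", DataError(f"blocks not in metadata: {sorted(missing)}")
        )
    seeds = _stage_seeds(
        config.seed,
        ["signal", "rates", "boot", "pls", "repeatability"],
    )

    # -- EFA ---------------------------------------------------------------
    def do_efa():
        base = Path(config.specimens).parent
        cache: dict[Path, dict] = {}
        coeff_rows = []
        per_block: dict[str, list] = {b: [] for b in blocks}
        for rec in meta.itertuples():
            if rec.trait not in per_block:
                continue
            path = (base / rec.outline_file).resolve()
            if path not in cache:
                cache[path] = dict(read_tps_outlines(path))
            outlines = cache[path]
            if rec.specimen_id not in outlines:
                raise DataError(
                    f"outline for specimen {rec.specimen_id!r} not found in {path}"
                )
            outline = outlines[rec.specimen_id]
            if config.flip_y:
                from .efa import Outline

                pts = outline.points.copy()
                pts[:, 1] *= -1
                outline = Outline(pts)
            coeffs = normalize_coefficients(
                compute_efa(outline, config.harmonics), mode=config.normalization
            )
            per_block[rec.trait].append((rec.specimen_id, coeffs))
            coeff_rows.append(
                {"specimen_id": rec.specimen_id, "trait": rec.trait}
                | dict(zip(_coef_cols(config.harmonics), coeffs.flatten()))
            )
        frame = pd.DataFrame(coeff_rows)
        write_table(frame, out_dir / "coeffs.csv")
        return {b: assemble_block(pairs, b) for b, pairs in per_block.items()}

    specimen_blocks = stage("efa")(do_efa)
    bundle["specimen_blocks"] = specimen_blocks

    # -- species means -------------------------------------------------------
    def do_means():
        means = {}
        frames = []
        for b in blocks:
            block = specimen_blocks[b]
            species = [
                meta.set_index("specimen_id").loc[sid, "species"]
                for sid in block.row_labels
            ]
            means[b] = species_mean_shapes(block, species, tree=tree)
            frame = means[b].to_frame().reset_index(names="species")
            frame.insert(0, "trait", b)
            frames.append(frame)
        write_table(pd.concat(frames, ignore_index=True), out_dir / "species_means.csv")
        return means

    means = stage("species_means")(do_means)
    bundle["species_means"] = means

    # -- phylogenetic signal -------------------------------------------------
    def do_signal():
        rows = []
        results = {}
        for i, b in enumerate(blocks):
            res = kmult_test(
                means[b], tree, n_permutations=config.n_perm,
                seed=seeds["signal"] + i,
            )
            results[b] = res
            rows.append(
                {
                    "trait": b,
                    "k_mult": res.k_mult,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                }
            )
        write_table(pd.DataFrame(rows), out_dir / "signal.csv")
        return results

    bundle["signal"] = stage("signal")(do_signal)

    # -- rates ---------------------------------------------------------------
    def do_rates():
        res = compare_rates(
            [means[b] for b in blocks],
            tree,
            n_simulations=config.n_sim,
            seed=seeds["rates"],
        )
        write_table(res.to_frame(), out_dir / "rates.csv")
        species_of = dict(zip(meta["specimen_id"], meta["species"]))
        cis = bootstrap_sigma2_ci(
            [specimen_blocks[b] for b in blocks],
            tree,
            species_of,
            n_boot=config.n_boot,
            seed=seeds["boot"],
        )
        ci_frame = pd.DataFrame(
            [dataclasses.asdict(ci) for ci in cis]
        )
        write_table(ci_frame, out_dir / "rate_cis.csv")
        return {"comparison": res, "cis": cis}

    bundle["rates"] = stage("rates")(do_rates)

    # -- integration ---------------------------------------------------------
    def do_pls():
        rows = []
        results = {}
        pair_idx = 0
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                a, b = blocks[i], blocks[j]
                res = phylo_pls(
                    means[a],
                    means[b],
                    tree,
                    n_permutations=config.pls_perm,
                    seed=seeds["pls"] + pair_idx,
                )
                pair_idx += 1
                results[(a, b)] = res
                rows.append(
                    {
                        "block1": a,
                        "block2": b,
                        "pls_corr": res.pls_corr,
                        "p_value": res.p_value,
                        "n_permutations": res.n_permutations,
                    }
                )
        write_table(pd.DataFrame(rows), out_dir / "pls.csv")
        return results

    bundle["pls"] = stage("pls")(do_pls)

    # -- specimen-level statistics -------------------------------------------
    def do_specimen_stats():
        meta_idx = meta.set_index("specimen_id")
        anova_rows = []
        rpt_rows = []
        pc1_species_means = {}
        for k, b in enumerate(blocks):
            block = specimen_blocks[b]
            pca = shape_pca(block, k=min(2, block.n_rows - 1, block.p))
            sub = meta_idx.loc[list(block.row_labels)]
            species = sub["species"].to_numpy()
            sizes = (
                sub["trait_size"].to_numpy()
                if "trait_size" in sub
                else np.ones(block.n_rows)
            )
            sexes = sub["sex"].to_numpy()
            use_sex = len(np.unique(sexes)) > 1
            for pc in range(pca.scores.shape[1]):
                scores = pca.scores[:, pc]
                try:
                    table = shape_effects_model(
                        scores, species, sizes, sex=sexes if use_sex else None
                    )
                    for row in table.frame.itertuples():
                        anova_rows.append(
                            {
                                "trait": b,
                                "pc": pc + 1,
                                "effect": row.effect,
                                "F": row.F,
                                "df_num": row.df_num,
                                "df_den": row.df_den,
                                "p_value": row.p_value,
                            }
                        )
                except DataError as exc:
                    logger.warning("ANOVA skipped for %s PC%d: %s", b, pc + 1, exc)
                rpt = repeatability(
                    scores,
                    species,
                    n_boot=config.n_boot,
                    n_perm=config.n_perm,
                    seed=seeds["repeatability"] + 10 * k + pc,
                )
                rpt_rows.append(
                    {
                        "trait": b,
                        "pc": pc + 1,
                        "icc": rpt.icc,
                        "se": rpt.se,
                        "ci_lower": rpt.ci_lower,
                        "ci_upper": rpt.ci_upper,
                        "p_value": rpt.p_value,
                    }
                )
            # species-mean PC1 for the traitgram / variance-ratio stages
            mean_pca = shape_pca(means[b], k=1)
            pc1_species_means[b] = pd.Series(
                mean_pca.scores[:, 0], index=list(means[b].row_labels)
            )
        write_table(pd.DataFrame(anova_rows), out_dir / "table1.csv")
        write_table(pd.DataFrame(rpt_rows), out_dir / "repeatability.csv")

        vr = None
        if len(blocks) >= 2:
            a, b = blocks[0], blocks[1]
            vr = variance_ratio_test(
                pc1_species_means[a].to_numpy(), pc1_species_means[b].to_numpy()
            )
            frame = vr.to_frame()
            frame.insert(0, "block2", b)
            frame.insert(0, "block1", a)
            write_table(frame, out_dir / "variance_ratio.csv")
        return {
            "anova": pd.DataFrame(anova_rows),
            "repeatability": pd.DataFrame(rpt_rows),
            "variance_ratio": vr,
            "pc1_species_means": pc1_species_means,
        }

    sstats = stage("specimen_stats")(do_specimen_stats)
    bundle["specimen_stats"] = sstats

    # -- ancestral states / traitgram -----------------------------------------
    def do_traitgram():
        from .phylo import ancestral_states, traitgram_coordinates

        anc_frames = []
        seg_frames = []
        for b in blocks[:2]:
            y = sstats["pc1_species_means"][b].reindex(list(tree.tip_labels))
            anc = ancestral_states(tree, y.to_numpy())
            frame = anc.frame.copy()
            frame.insert(0, "trait", b)
            anc_frames.append(frame)
            segs = traitgram_coordinates(tree, y.to_numpy())
            segs.insert(0, "trait", b)
            seg_frames.append(segs)
        write_table(pd.concat(anc_frames, ignore_index=True), out_dir / "ancestral.csv")
        write_table(pd.concat(seg_frames, ignore_index=True), out_dir / "traitgram.csv")
        return {"ancestral": anc_frames, "traitgram": seg_frames}

    bundle["traitgram"] = stage("traitgram")(do_traitgram)

    # -- run log ---------------------------------------------------------------
    log_lines = [f"morphorates {__version__}", f"numpy {np.__version__}"]
    log_lines += [
        f"{f.name} = {getattr(config, f.name)}" for f in dataclasses.fields(config)
    ]
    log_lines += [f"stage_seed {k} = {v}" for k, v in sorted(seeds.items())]
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return bundle


def _coef_cols(n_harmonics: int) -> list[str]:
    from .efa import coefficient_column_labels

    return coefficient_column_labels(n_harmonics)
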