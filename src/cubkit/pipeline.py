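"""Study-shaped analysis pipeline and run reporting.

`run_pipeline` drives the full workflow on a set of FASTA inputs:
deduplication, per-sequence metrics, pooled per-group RSCU with
preferred/over/under classification, PR2 coordinates, neutrality
regressions with the mutation/selection split, Spearman correlation
matrices, RSCU-space PCA and the CAI group comparison.  Every table is
written as TSV into a run directory together with a manifest (config,
package version, artifact checksums) so any run is reproducible from
its artifacts.  `write_report` renders a single human-readable summary
from a completed run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codon_stats import (
    cai,
    classify_rscu,
    composition_summary,
    count_codons,
    metrics_table,
    pool_counts,
    rscu_profile,
)
from .genetic_code import to_rna
from .multivariate import pca_rscu, rscu_matrix
from .selection_forces import (
    cai_group_comparison,
    neutrality_fit,
    pr2_coordinates,
    spearman_matrix,
)
from .sequence_io import (
    CodingSequence,
    deduplicate,
    read_fasta,
    read_reference_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    ``inputs`` maps FASTA paths to group labels (labels are metadata
    supplied by the user, never parsed from sequence content).
    ``gc3_mode`` selects the neutrality-plot abscissa: "all" uses
    GC3 over all codons, "synonymous" uses GC3s.
    """

    inputs: dict[str, str]
    reference_table: str | None = None
    reference_units: str = "count"
    outlier_method: str = "tukey"
    gc3_mode: str = "all"
    alpha: float = 0.05
    seed: int = 0
    dedup: bool = True
    strict: bool = True
    out_dir: str = "cubkit_run"
    plots: bool = False

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _neutrality_row(name: str, fit) -> dict:
    return {
        "group": name,
        "n_used": fit.n_used,
        "n_removed": fit.n_removed,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "pearson_r": fit.pearson_r,
        "pearson_p": fit.pearson_p,
        "spearman_rho": fit.spearman_rho,
        "spearman_p": fit.spearman_p,
        "selection_pct": fit.selection_pct,
        "mutation_pct": fit.mutation_pct,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the run directory.

    Any stage failure aborts with the stage name in the exception
    message.  See the module docstring for the artifact list.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("cubkit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    stage = "input"
    try:
        seqs: list[CodingSequence] = []
        for path, group in config.inputs.items():
            seqs.extend(read_fasta(path, group=group, strict=config.strict))
        if not seqs:
            raise ValueError("no input sequences")
        if config.dedup:
            stage = "deduplicate"
            before = len(seqs)
            seqs = deduplicate(seqs)
            logger.info("dedup: %d -> %d sequences", before, len(seqs))

        ref = None
        if config.reference_table:
            stage = "reference table"
            ref = read_reference_table(
                config.reference_table, units=config.reference_units
            )

        groups = sorted({s.group for s in seqs})

        stage = "per-sequence metrics"
        metrics = metrics_table(seqs, ref=ref)
        _write_tsv(metrics, out / "metrics.tsv")
        rounded = metrics.copy()
        for col in rounded.columns:
            if rounded[col].dtype.kind == "f":
                rounded[col] = rounded[col].round(2)
        _write_tsv(rounded, out / "metrics_2dp.tsv")

        stage = "pooled RSCU"
        class_rows = []
        rscu_cols = {}
        for g in groups:
            pooled = pool_counts([s for s in seqs if s.group == g], source=g)
            profile = rscu_profile(pooled)
            rscu_cols[g] = profile.as_series()
            cls = classify_rscu(profile, reference=ref)
            class_rows.append(
                {
                    "group": g,
                    "preferred": ",".join(
                        sorted(to_rna(c) for c in cls.preferred_set)
                    ),
                    "over_represented": ",".join(sorted(to_rna(c) for c in cls.over)),
                    "under_represented": ",".join(
                        sorted(to_rna(c) for c in cls.under)
                    ),
                }
            )
        rscu_table = pd.DataFrame(rscu_cols)
        rscu_table.index.name = "codon"
        _write_tsv(rscu_table.round(4), out / "rscu_by_group.tsv", index=True)
        _write_tsv(pd.DataFrame(class_rows), out / "codon_classification.tsv")

        stage = "PR2"
        pr2_rows = []
        comps = {s.id: composition_summary(s) for s in seqs}
        for s in seqs:
            p = pr2_coordinates(comps[s.id], source=s.id)
            pr2_rows.append(
                {
                    "id": s.id,
                    "group": s.group,
                    "at_bias": p.at_bias,
                    "gc_bias": p.gc_bias,
                }
            )
        _write_tsv(pd.DataFrame(pr2_rows), out / "pr2_points.tsv")

        stage = "neutrality"
        gc3_col = "GC3%" if config.gc3_mode == "all" else "GC3s"
        fits = []
        scale = 1.0 if config.gc3_mode == "all" else 100.0
        overall = neutrality_fit(
            metrics["GC12%"], metrics[gc3_col] * scale, config.outlier_method
        )
        fits.append(_neutrality_row("overall", overall))
        for g in groups:
            sub = metrics[metrics["group"] == g]
            try:
                fits.append(
                    _neutrality_row(
                        g,
                        neutrality_fit(
                            sub["GC12%"], sub[gc3_col] * scale, config.outlier_method
                        ),
                    )
                )
            except ValueError as e:
                logger.warning("neutrality fit skipped for %s: %s", g, e)
        _write_tsv(pd.DataFrame(fits), out / "neutrality_fit.tsv")

        stage = "correlations"
        corr_frames = []
        for g in groups:
            sub = metrics[metrics["group"] == g]
            if len(sub) < 5:
                logger.warning("correlations skipped for %s (n=%d < 5)", g, len(sub))
                continue
            m = spearman_matrix(sub)
            annotated = m.annotated()
            annotated.insert(0, "group", g)
            annotated.insert(1, "variable", annotated.index)
            corr_frames.append(annotated)
        if corr_frames:
            _write_tsv(
                pd.concat(corr_frames, ignore_index=True),
                out / "correlation_matrix.tsv",
            )

        stage = "PCA"
        if len(seqs) >= 3:
            mat = rscu_matrix(seqs)
            k = min(2, len(seqs) - 1)
            pca = pca_rscu(mat, k=k)
            scores = pca.scores.copy()
            scores.insert(0, "group", mat.groups)
            scores.index.name = "id"
            _write_tsv(scores, out / "pca_scores.tsv", index=True)
            _write_tsv(
                pd.DataFrame(
                    {
                        "component": [f"PC{i+1}" for i in range(k)],
                        "variance_fraction": pca.explained_variance_ratio,
                    }
                ),
                out / "pca_variance.tsv",
            )
            loadings = pca.loadings.copy()
            loadings.index.name = "codon"
            _write_tsv(loadings, out / "pca_loadings.tsv", index=True)

        stage = "CAI group comparison"
        if ref is not None and len(groups) >= 2:
            by_group = {
                g: metrics.loc[metrics["group"] == g, "CAI"].tolist() for g in groups
            }
            if all(len(v) >= 3 for v in by_group.values()):
                cmp_res = cai_group_comparison(by_group, alpha=config.alpha)
                _write_tsv(cmp_res.pairwise, out / "cai_pairwise.tsv")
                _write_tsv(
                    pd.DataFrame(
                        {
                            "group": groups,
                            "n": [len(by_group[g]) for g in groups],
                            "cai_mean": [
                                float(pd.Series(by_group[g]).mean()) for g in groups
                            ],
                            "cai_sd": [
                                float(pd.Series(by_group[g]).std(ddof=1))
                                for g in groups
                            ],
                            "letters": [cmp_res.letters[g] for g in groups],
                        }
                    ),
                    out / "cai_groups.tsv",
                )
            else:
                logger.warning("CAI comparison skipped: a group has < 3 sequences")

        if config.plots:
            stage = "plots"
            _make_plots(out, metrics, gc3_col)

        stage = "manifest"
        config.to_yaml(out / "config.yaml")
        artifacts = sorted(
            p.name for p in out.iterdir() if p.suffix == ".tsv"
        )
        manifest = {
            "cubkit_version": __version__,
            "config_sha256": _sha256(out / "config.yaml"),
            "n_sequences": len(seqs),
            "groups": groups,
            "artifacts": {a: _sha256(out / a) for a in artifacts},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _make_plots(out: Path, metrics: pd.DataFrame, gc3_col: str) -> None:
    """Optional diagnostic figures (headless-safe, PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    from .codon_stats import expected_enc

    fig, ax = plt.subplots(figsize=(5, 4))
    s = np.linspace(0.0, 1.0, 201)
    ax.plot(s, [expected_enc(v) for v in s], "k-", lw=1, label="expected")
    for g, sub in metrics.groupby("group"):
        ax.scatter(sub["GC3s"], sub["ENC"], s=12, label=g or "all")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "enc_plot.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, sub in metrics.groupby("group"):
        ax.scatter(sub[gc3_col], sub["GC12%"], s=12, label=g or "all")
    ax.set_xlabel(gc3_col)
    ax.set_ylabel("GC12%")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "neutrality_plot.png", dpi=150)
    plt.close(fig)


def write_report(run_dir: str | Path) -> Path:
    """Render summary.md for a completed run; returns its path.

    The summary cites every TSV artifact, states the neutrality
    mutation/selection split per group, and verifies artifact
    checksums against the manifest (mismatches produce an integrity
    warning in the summary, not an exception).
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}")
    manifest = json.loads(manifest_path.read_text())

    lines = ["# Codon usage analysis summary", ""]
    lines.append(f"cubkit {manifest['cubkit_version']}; "
                 f"{manifest['n_sequences']} sequences; "
                 f"groups: {', '.join(manifest['groups'])}")
    lines.append("")

    warnings_ = []
    for name, digest in manifest["artifacts"].items():
        p = run_dir / name
        if not p.exists():
            warnings_.append(f"missing artifact {name}")
        elif _sha256(p) != digest:
            warnings_.append(f"checksum mismatch for {name} (tampered or regenerated)")
    if warnings_:
        lines.append("## Integrity warnings")
        lines += [f"- {w}" for w in warnings_]
        lines.append("")

    lines.append("## Artifacts")
    lines += [f"- `{name}`" for name in manifest["artifacts"]]
    lines.append("")

    neut = run_dir / "neutrality_fit.tsv"
    if neut.exists():
        df = pd.read_csv(neut, sep="\t")
        lines.append("## Neutrality plot")
        for _, r in df.iterrows():
            lines.append(
                f"- {r['group']}: slope {r['slope']:.4g} "
                f"(n={int(r['n_used'])}, {int(r['n_removed'])} outliers removed); "
                f"natural selection contributes {r['selection_pct']:.2f}% and "
                f"mutation pressure {r['mutation_pct']:.2f}% to the codon usage pattern."
            )
        lines.append("")

    cai_path = run_dir / "cai_groups.tsv"
    if cai_path.exists():
        df = pd.read_csv(cai_path, sep="\t")
        lines.append("## CAI by group")
        for _, r in df.iterrows():
            lines.append(
                f"- {r['group']}: CAI {r['cai_mean']:.3f} ± {r['cai_sd']:.3f} "
                f"(n={int(r['n'])}, letter '{r['letters']}')"
            )
        lines.append("")
    elif len(manifest["groups"]) < 2:
        lines.append("## CAI by group")
        lines.append("- not applicable: fewer than two groups")
        lines.append("")

    out = run_dir / "summary.md"
    out.write_text("\n".join(lines))
    return out
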