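"""End-to-end orchestration: per-organism index tables, Δ-metrics, statistics.

A run is described by a single declarative YAML file (see `RunConfig`). The
data directory holds one CDS FASTA per organism (``<name>.cds.fasta``), one
generic tRNA-pool TSV per host (``<name>.trna.tsv``) and a phage metadata TSV
in the bundled-table schema; phage tAI is always computed against the host's
pool. Outputs are tidy TSVs plus a JSON manifest recording the config hash,
seeds, QC counts, adjustment families, and skipped contrasts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparative, indices, stats
from .metadata import Lifestyle, classify_trna_group, load_phage_table
from .seqio import QCLog, read_cds_fasta, read_trna_pool

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_indices", "run_comparisons", "report", "run_all"]

GC_TYPES = ("delta_gc_total", "delta_gc1", "delta_gc2", "delta_gc3")


@dataclass
class RunConfig:
    data_dir: Path
    outdir: Path
    hosts: list[str]
    metadata_file: str = "phage_table.tsv"
    seed: int = 1
    epsilon: float = indices.EPSILON
    n_perm_permanova: int = 9_999
    n_perm_wilcoxon: int = 10_000
    adjust_gc: str = "bonferroni"
    adjust_enc: str = "BH"
    adjust_rscu: str = "BH"
    tai_summary: str = "mean"
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["data_dir"] = Path(raw["data_dir"])
        raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Provenance hash over analysis parameters (file locations excluded)."""
        payload = {
            k: str(v)
            for k, v in sorted(self.__dict__.items())
            if k not in ("data_dir", "outdir")
        }
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:12]

    def validate(self) -> None:
        meta = self.data_dir / self.metadata_file
        if not meta.exists():
            raise FileNotFoundError(f"metadata table not found: {meta}")
        for host in self.hosts:
            for suffix in (".cds.fasta", ".trna.tsv"):
                p = self.data_dir / f"{host}{suffix}"
                if not p.exists():
                    raise FileNotFoundError(f"missing host file for {host!r}: {p}")


def _index_path(cfg: RunConfig, organism: str) -> Path:
    return cfg.outdir / "indices" / f"{organism}.indices.tsv"


def _rscu_path(cfg: RunConfig, organism: str) -> Path:
    return cfg.outdir / "indices" / f"{organism}.rscu_mean.tsv"


def _host_for(cfg: RunConfig, genus: str) -> str:
    matches = [h for h in cfg.hosts if h.lower() == genus.lower()]
    if not matches:
        raise ValueError(f"no configured host for genus {genus!r}")
    return matches[0]


def _organisms(cfg: RunConfig) -> tuple[list, dict[str, str]]:
    """(phage records, organism -> host name) for everything in the run."""
    records = load_phage_table(cfg.data_dir / cfg.metadata_file)
    host_of = {r.name: _host_for(cfg, r.host_genus) for r in records}
    return records, host_of


def run_indices(cfg: RunConfig, resume: bool = True) -> dict[str, QCLog]:
    """Per-gene index tables (and genome-mean RSCU) for every organism.

    Deterministic given inputs; with ``resume`` organisms whose output is
    newer than their input FASTA are skipped.
    """
    cfg.validate()
    (cfg.outdir / "indices").mkdir(parents=True, exist_ok=True)
    records, host_of = _organisms(cfg)
    pools = {h: read_trna_pool(cfg.data_dir / f"{h}.trna.tsv") for h in cfg.hosts}
    qc: dict[str, QCLog] = {}
    jobs = [(h, h) for h in cfg.hosts] + [(r.name, host_of[r.name]) for r in records]
    for organism, host in jobs:
        fasta = cfg.data_dir / f"{organism}.cds.fasta"
        if not fasta.exists():
            raise FileNotFoundError(
                f"missing CDS FASTA for organism {organism!r}: {fasta}"
            )
        out = _index_path(cfg, organism)
        if resume and out.exists() and out.stat().st_mtime >= fasta.stat().st_mtime:
            logger.info("indices up to date for %s, skipping", organism)
            continue
        log = QCLog()
        cds = read_cds_fasta(fasta, log)
        qc[organism] = log
        table = indices.genome_index_table(
            organism, cds, pool=pools[host], epsilon=cfg.epsilon
        )
        table.to_csv(out, sep="\t", index=False, float_format="%.10g")
        vectors = [indices.rscu(indices.count_codons(c)) for c in cds]
        mean_vec = indices.mean_rscu(vectors)
        pd.DataFrame(
            {"codon": list(mean_vec.values), "mean_rscu": list(mean_vec.values.values())}
        ).to_csv(_rscu_path(cfg, organism), sep="\t", index=False, float_format="%.10g")
    return qc


def _load_mean_rscu(cfg: RunConfig, organism: str) -> indices.RSCUVector:
    df = pd.read_csv(_rscu_path(cfg, organism), sep="\t")
    return indices.RSCUVector(
        values=dict(zip(df["codon"], df["mean_rscu"])), scope="per_genome_mean"
    )


def build_delta_records(cfg: RunConfig) -> list[comparative.DeltaRecord]:
    records, host_of = _organisms(cfg)
    host_tables = {h: pd.read_csv(_index_path(cfg, h), sep="\t") for h in cfg.hosts}
    out = []
    for rec in records:
        host = host_of[rec.name]
        pt = pd.read_csv(_index_path(cfg, rec.name), sep="\t")
        ht = host_tables[host]
        dgc = {
            key: 100.0 * (pt[col].mean() - ht[col].mean())
            for key, col in (
                ("delta_gc_total", "gc_total"),
                ("delta_gc1", "gc1"),
                ("delta_gc2", "gc2"),
                ("delta_gc3", "gc3"),
            )
        }
        denc = float(pt["enc"].dropna().mean() - ht["enc"].dropna().mean())
        drscu = comparative.delta_rscu(
            _load_mean_rscu(cfg, rec.name), _load_mean_rscu(cfg, host)
        )
        host_summary = (
            ht["tai_final"].mean()
            if cfg.tai_summary == "mean"
            else ht["tai_final"].median()
        )
        per_gene = (pt["tai_final"] - host_summary).tolist()
        out.append(
            comparative.DeltaRecord(
                phage_id=rec.name,
                host_id=host,
                genus=rec.host_genus,
                lifestyle=rec.lifestyle,
                trna_group=classify_trna_group(rec.n_trna),
                **dgc,
                delta_enc=denc,
                delta_rscu=drscu,
                delta_tai_per_gene=per_gene,
                delta_tai_mean=float(np.mean(per_gene)),
                delta_tai_median=float(np.median(per_gene)),
            )
        )
    return out


def _two_arm_values(
    records: list[comparative.DeltaRecord], arm: tuple[str, ...], attr: str
) -> list[float]:
    vals = []
    for r in records:
        labels = {r.lifestyle.value, r.trna_group.value}
        if labels & set(arm):
            vals.append(getattr(r, attr))
    return vals


def run_comparisons(cfg: RunConfig) -> dict:
    """Δ tables, contrast statistics, PERMANOVA/PCA and Nc-plot data files."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    records = build_delta_records(cfg)
    chash = cfg.config_hash()

    delta_rows = []
    rscu_rows = []
    tai_rows = []
    for r in records:
        delta_rows.append(
            {
                "phage_id": r.phage_id, "host_id": r.host_id, "genus": r.genus,
                "lifestyle": r.lifestyle.value, "trna_group": r.trna_group.value,
                **{k: getattr(r, k) for k in GC_TYPES},
                "delta_enc_mean": r.delta_enc,
                "delta_tai_mean": r.delta_tai_mean,
                "delta_tai_median": r.delta_tai_median,
                "config_hash": chash,
            }
        )
        for codon, v in r.delta_rscu.items():
            rscu_rows.append({"phage_id": r.phage_id, "codon": codon, "delta_rscu": v})
        for i, v in enumerate(r.delta_tai_per_gene):
            tai_rows.append(
                {
                    "phage_id": r.phage_id, "gene_index": i, "delta_tai": v,
                    "lifestyle": r.lifestyle.value, "trna_group": r.trna_group.value,
                    "host": r.host_id,
                }
            )
    pd.DataFrame(delta_rows).to_csv(cfg.outdir / "delta_table.tsv", sep="\t", index=False)
    rscu_long = pd.DataFrame(rscu_rows)
    rscu_long.to_csv(cfg.outdir / "delta_rscu_long.tsv", sep="\t", index=False)
    tai_long = pd.DataFrame(tai_rows)
    tai_long.to_csv(cfg.outdir / "delta_tai_long.tsv", sep="\t", index=False)

    # contrast statistics on scalar deltas
    contrast_rows = []
    skipped = []
    metrics = list(GC_TYPES) + ["delta_enc"]
    for contrast, (arm_a, arm_b) in comparative.CONTRASTS.items():
        for metric in metrics:
            a = _two_arm_values(records, arm_a, metric)
            b = _two_arm_values(records, arm_b, metric)
            if not a or not b:
                skipped.append({"contrast": contrast, "metric": metric})
                continue
            res = stats.wilcoxon_rank_sum(a, b)
            contrast_rows.append(
                {
                    "scope": "global", "contrast": contrast, "metric": metric,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "effect_size": res.effect_size, "n_a": len(a), "n_b": len(b),
                    "adjust_method": "none", "config_hash": chash,
                }
            )
    # family-wise adjustment within each metric across contrasts
    cdf = pd.DataFrame(contrast_rows)
    if not cdf.empty:
        for metric, sub in cdf.groupby("metric"):
            m = cfg.adjust_enc if metric == "delta_enc" else cfg.adjust_gc
            cdf.loc[sub.index, "adjusted_p"] = stats.adjust_pvalues(
                sub["p_value"].to_numpy(), m
            )
            cdf.loc[sub.index, "adjust_method"] = m
    cdf.to_csv(cfg.outdir / "contrast_stats.tsv", sep="\t", index=False)

    # Kruskal-Wallis + Dunn across the three tRNA groups per metric
    kw_rows = []
    for metric in metrics:
        groups = {
            g: [getattr(r, metric) for r in records if r.trna_group.value == g]
            for g in ("High", "Low", "None")
        }
        groups = {g: v for g, v in groups.items() if v}
        if len(groups) < 2:
            skipped.append({"contrast": "kruskal_trna_groups", "metric": metric})
            continue
        kw = stats.kruskal_wallis(list(groups.values()))
        kw_rows.append(
            {
                "metric": metric, "test": "kruskal", "statistic": kw.H,
                "p_value": kw.p_value, "eta2_H": kw.eta2_H, "N": kw.N,
            }
        )
        if len(groups) > 2:
            adj = "bonferroni" if metric.startswith("delta_gc") else cfg.adjust_enc
            for res in stats.dunn_posthoc(groups, adjust=adj):
                kw_rows.append(
                    {
                        "metric": metric, "test": f"dunn:{res.label}",
                        "statistic": res.statistic, "p_value": res.p_value,
                        "adjusted_p": res.adjusted_p, "effect_size": res.effect_size,
                    }
                )
    pd.DataFrame(kw_rows).to_csv(cfg.outdir / "trna_group_stats.tsv", sep="\t", index=False)

    # per-codon ΔRSCU tests: permutation Wilcoxon by lifestyle, KW by tRNA group
    codon_rows = []
    labels = {r.phage_id: r for r in records}
    if not rscu_long.empty:
        for codon, sub in rscu_long.groupby("codon"):
            vir = [
                v for p, v in zip(sub["phage_id"], sub["delta_rscu"])
                if labels[p].lifestyle is Lifestyle.VIRULENT
            ]
            tem = [
                v for p, v in zip(sub["phage_id"], sub["delta_rscu"])
                if labels[p].lifestyle is Lifestyle.TEMPERATE
            ]
            row = {"codon": codon}
            if vir and tem:
                codon_seed = cfg.seed + int.from_bytes(codon.encode(), "big") % 100_003
                res = stats.permutation_wilcoxon(
                    vir, tem, n_perm=cfg.n_perm_wilcoxon, seed=codon_seed
                )
                row.update(
                    lifestyle_p=res.p_value, lifestyle_effect=res.effect_size,
                    n_virulent=len(vir), n_temperate=len(tem),
                )
            grp = {
                g: [
                    v for p, v in zip(sub["phage_id"], sub["delta_rscu"])
                    if labels[p].trna_group.value == g
                ]
                for g in ("High", "Low", "None")
            }
            grp = {g: v for g, v in grp.items() if v}
            if len(grp) >= 2:
                kw = stats.kruskal_wallis(list(grp.values()))
                row.update(trna_kw_p=kw.p_value, trna_eta2_H=kw.eta2_H)
            codon_rows.append(row)
        codon_df = pd.DataFrame(codon_rows)
        for col, out_col in (("lifestyle_p", "lifestyle_p_bh"), ("trna_kw_p", "trna_kw_p_bh")):
            if col in codon_df:
                mask = codon_df[col].notna()
                codon_df.loc[mask, out_col] = stats.adjust_pvalues(
                    codon_df.loc[mask, col].to_numpy(), "BH"
                )
        codon_df.to_csv(cfg.outdir / "rscu_codon_stats.tsv", sep="\t", index=False)

    # PERMANOVA on the phage x codon ΔRSCU matrix, plus PCA scores
    permanova_out: dict = {}
    if not rscu_long.empty:
        mat = rscu_long.pivot(index="phage_id", columns="codon", values="delta_rscu")
        mat = mat.dropna(axis=1)
        fac = pd.DataFrame(
            {
                "trna_group": [labels[p].trna_group.value for p in mat.index],
                "lifestyle": [labels[p].lifestyle.value for p in mat.index],
            },
            index=mat.index,
        )
        testable = [c for c in fac.columns if fac[c].nunique() >= 2]
        try:
            res = stats.permanova(
                mat, fac[testable], n_perm=cfg.n_perm_permanova, seed=cfg.seed
            )
            permanova_out = {
                "factors": res.factors, "r2": res.r2, "pseudo_f": res.pseudo_f,
                "p_values": res.p_values, "residual_r2": res.residual_r2,
                "dispersion_p": res.dispersion_p, "mode": "joint",
            }
        except ValueError:
            # confounded design: fall back to single-factor models
            permanova_out = {"mode": "single_factor_fallback", "factors": {}}
            for c in testable:
                res = stats.permanova(
                    mat, fac[[c]], n_perm=cfg.n_perm_permanova, seed=cfg.seed
                )
                permanova_out["factors"][c] = {
                    "r2": res.r2[c], "pseudo_f": res.pseudo_f[c],
                    "p_value": res.p_values[c], "dispersion_p": res.dispersion_p[c],
                }
        with open(cfg.outdir / "permanova.json", "w") as fh:
            json.dump(permanova_out, fh, indent=2, default=str)
        scores = stats.pca_scores(mat)
        scores["lifestyle"] = fac["lifestyle"]
        scores["trna_group"] = fac["trna_group"]
        scores.to_csv(cfg.outdir / "pca_scores.tsv", sep="\t")

    # Nc-plot data over all organisms
    idx_tables = []
    recs, host_of = _organisms(cfg)
    for rec in recs:
        t = pd.read_csv(_index_path(cfg, rec.name), sep="\t")
        t["genus"] = rec.host_genus
        t["lifestyle"] = rec.lifestyle.value
        t["trna_group"] = classify_trna_group(rec.n_trna).value
        idx_tables.append(t)
    for h in cfg.hosts:
        t = pd.read_csv(_index_path(cfg, h), sep="\t")
        t["genus"] = h.title()
        idx_tables.append(t)
    ncdata = comparative.nc_plot_data(pd.concat(idx_tables, ignore_index=True))
    ncdata.to_csv(cfg.outdir / "nc_plot_data.tsv", sep="\t", index=False)

    # ΔtAI beta-model design (per-gene, rescaled); fitting is delegated
    if not tai_long.empty:
        spec = stats.build_beta_model_spec(tai_long, scope="global", epsilon=cfg.epsilon)
        design = spec.fixed.copy()
        design.insert(0, "response_rescaled", spec.response)
        design["phage_id"] = spec.groups
        design.to_csv(cfg.outdir / "beta_model_design.tsv", sep="\t", index=False)

    manifest = {
        "config_hash": chash,
        "seed": cfg.seed,
        "n_perm_permanova": cfg.n_perm_permanova,
        "n_perm_wilcoxon": cfg.n_perm_wilcoxon,
        "contrasts": list(comparative.CONTRASTS),
        "levels": ["per_genus", "global"],
        "skipped": skipped,
        "adjustments": {
            "gc": cfg.adjust_gc, "enc": cfg.adjust_enc, "rscu": cfg.adjust_rscu,
        },
        "permanova": permanova_out.get("mode", "not_run"),
        "n_phages": len(records),
    }
    with open(cfg.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def report(cfg: RunConfig) -> list[Path]:
    """Optional plot files; the data they render comes from the TSV outputs."""
    if not cfg.make_plots:
        return []
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = []
    plots = cfg.outdir / "plots"
    plots.mkdir(parents=True, exist_ok=True)

    ncdata = pd.read_csv(cfg.outdir / "nc_plot_data.tsv", sep="\t")
    s = np.linspace(0, 1, 512)
    fig, ax = plt.subplots()
    ax.plot(s, [indices.wright_expected_nc(v) for v in s], "k-", lw=1, label="expected")
    ax.scatter(ncdata["gc3"], ncdata["enc"], s=4, alpha=0.4)
    ax.set_xlabel("GC3")
    ax.set_ylabel("EnC")
    ax.legend()
    p = plots / "nc_plot.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out.append(p)

    pca_file = cfg.outdir / "pca_scores.tsv"
    if pca_file.exists():
        scores = pd.read_csv(pca_file, sep="\t", index_col=0)
        fig, ax = plt.subplots()
        for ls, sub in scores.groupby("lifestyle"):
            ax.scatter(sub["PC1"], sub["PC2"], label=ls, s=20)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        p = plots / "pca_delta_rscu.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        out.append(p)
    return out


def run_all(cfg: RunConfig) -> dict:
    run_indices(cfg)
    manifest = run_comparisons(cfg)
    report(cfg)
    return manifest
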