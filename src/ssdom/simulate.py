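"""Synthetic reciprocal-cross expression data with known truth.

Emulates the post-quantification structure of an abdomen RNA-seq
experiment on crosses between pairs of homozygous (isogenic) lines: for
each cross, 3 biological replicates of each of the 4 genotypes (two
parental homozygotes and the two reciprocal F1 heterozygotes) in both
sexes, i.e. 24 samples per cross.  The generated features are

* strong genome-wide sex-biased expression (roughly half of all genes),
* parental line differences in about half of the genes, a subset of which
  are sexually discordant (line effect differs between the sexes),
* dominance of the heterozygote relative to the arithmetic midparent,
  injected on the natural scale so that the per-sex dominance coefficient
  delta_s = ln(het_s / midparent_s) is the generating parameter itself;
  a minority of line-different genes get sex-specific dominance
  (independent per-sex deltas),
* rare parent-of-origin effects (reciprocal heterozygotes differ),
* X hemizygosity in males (heterozygous males express the dam line's
  level) and male-limited Y expression,
* log-normal library-size variation, and
* occasional whole-sample mis-sexing (counts generated with the opposite
  sex while the annotation keeps the recorded sex).

Counts are negative binomial via a gamma-Poisson mixture with per-gene
dispersion.  The same seed always yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import CountMatrix
from .errors import ConfigError, ValidationError

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")

LN2 = float(np.log(2.0))


@dataclass
class SimConfig:
    """Generator settings; defaults describe the study design emulated.

    Effect sizes are in log2 units except the dominance deltas (natural
    log, the estimand's own scale) and the parent-of-origin effect
    (natural log fold between reciprocal heterozygotes).
    """

    n_genes: int = 2500
    n_reps: int = 3
    crosses: tuple[tuple[str, str], ...] = (("A", "B"), ("C", "D"), ("E", "F"))
    # sex-biased expression: ~half the genome, strong effects
    prop_sex_biased: float = 0.5
    sex_effect_log2: tuple[float, float] = (0.5, 6.0)
    # parental line differences
    prop_line_diff: float = 0.5
    additive_effect_log2: tuple[float, float] = (0.25, 2.0)
    # fraction of line-different genes whose line effect is sexually
    # discordant (independent per-sex draws) -- these fail the
    # sex-concordance filter by construction
    prop_line_discordant: float = 0.3
    # fraction of concordant line-different genes with sex-specific dominance
    prop_ssd: float = 0.1
    delta_sd_concordant: float = 0.3
    delta_sd_ssd: float = 0.5
    delta_max: float = 1.2
    # parent-of-origin effects
    prop_poe: float = 0.02
    poe_ln: tuple[float, float] = (0.35, 1.0)
    # NB dispersion (pooled isogenic replicates are tight)
    dispersion_meanlog: float = float(np.log(0.02))
    dispersion_sdlog: float = 0.6
    dispersion_range: tuple[float, float] = (1e-4, 0.5)
    # baseline expression and library sizes
    baseline_log2_range: tuple[float, float] = (4.0, 10.0)
    libsize_sdlog: float = 0.3
    # chromosome classes
    prop_x_linked: float = 0.10
    prop_y_linked: float = 0.02
    # whole-sample mis-sexing (across all crosses)
    n_mis_sexed: int = 2
    seed: int = 0

    def validate(self) -> None:
        props = {
            "prop_sex_biased": self.prop_sex_biased,
            "prop_line_diff": self.prop_line_diff,
            "prop_line_discordant": self.prop_line_discordant,
            "prop_ssd": self.prop_ssd,
            "prop_poe": self.prop_poe,
            "prop_x_linked": self.prop_x_linked,
            "prop_y_linked": self.prop_y_linked,
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.prop_x_linked + self.prop_y_linked > 1.0:
            raise ConfigError("prop_x_linked + prop_y_linked exceeds 1")
        for name in ("sex_effect_log2", "additive_effect_log2", "poe_ln",
                     "baseline_log2_range", "dispersion_range"):
            lo, hi = getattr(self, name)
            if lo < 0 and name != "baseline_log2_range":
                raise ConfigError(f"{name} lower bound must be >= 0")
            if hi < lo:
                raise ConfigError(f"{name} bounds out of order")
        if self.n_genes < 1 or self.n_reps < 1:
            raise ConfigError("n_genes and n_reps must be positive")
        if self.n_mis_sexed < 0:
            raise ConfigError("n_mis_sexed must be >= 0")
        total = 2 * 4 * self.n_reps * len(self.crosses)
        if self.n_mis_sexed > total:
            raise ConfigError("n_mis_sexed exceeds the number of samples")
        for pair in self.crosses:
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ConfigError(f"cross {pair} must name two distinct lines")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["crosses"] = [list(p) for p in self.crosses]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "crosses" in d:
            d["crosses"] = tuple(tuple(p) for p in d["crosses"])
        for key in ("sex_effect_log2", "additive_effect_log2", "poe_ln",
                    "baseline_log2_range", "dispersion_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _truncnorm(rng: np.random.Generator, sd: float, bound: float, size: int) -> np.ndarray:
    """Normal(0, sd) truncated to [-bound, bound] by resampling."""
    if sd == 0:
        return np.zeros(size)
    out = rng.normal(0.0, sd, size)
    bad = np.abs(out) > bound
    while bad.any():
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) > bound
    return out


def _signed_uniform(rng, lo, hi, size):
    return rng.uniform(lo, hi, size) * rng.choice([-1.0, 1.0], size)


def simulate_cross(config: SimConfig):
    """Generate (CountMatrix, sample table, gene table, truth table).

    Truth has one row per gene per cross (one per gene under the default
    single-cross config); effects are drawn independently for each cross,
    mirroring crosses between different line pairs exposing different
    variants.  The sample table carries a `generated_sex` column (ground
    truth for mis-sexed samples) that the analysis pipeline never reads.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ng = config.n_genes

    gene_ids = [f"g{i:05d}" for i in range(ng)]
    u = rng.random(ng)
    chrom = np.where(u < config.prop_y_linked, "Y",
                     np.where(u < config.prop_y_linked + config.prop_x_linked, "X",
                              "autosome"))
    genes = pd.DataFrame({"gene_id": gene_ids, "chrom_class": chrom})

    # ---- sample sheet -------------------------------------------------
    rows = []
    for ci, (l1, l2) in enumerate(config.crosses):
        cross_id = _ROMAN[ci] if ci < len(_ROMAN) else f"C{ci + 1}"
        for dam, sire in ((l1, l1), (l2, l2), (l1, l2), (l2, l1)):
            for sex in ("female", "male"):
                for rep in range(1, config.n_reps + 1):
                    rows.append({
                        "sample_id": f"{cross_id}_{dam}{sire}_{sex[0]}{rep}",
                        "sex": sex, "dam": dam, "sire": sire,
                        "cross": cross_id, "replicate": rep,
                    })
    samples = pd.DataFrame(rows)
    samples["genotype"] = samples["dam"] + samples["sire"]
    samples["homozygous"] = samples["dam"] == samples["sire"]
    samples["excluded"] = False
    samples["exclude_reason"] = ""
    samples["generated_sex"] = samples["sex"]
    if config.n_mis_sexed > 0:
        flip = rng.choice(len(samples), size=config.n_mis_sexed, replace=False)
        swapped = samples["generated_sex"].to_numpy().copy()
        for i in flip:
            swapped[i] = "male" if swapped[i] == "female" else "female"
        samples["generated_sex"] = swapped

    # ---- per-gene truth -------------------------------------------------
    # baseline abundance, sex bias and dispersion are gene properties,
    # shared across crosses; genetic (line) effects, dominance and POE are
    # cross-specific, since each line pair exposes different variants
    base_ln = rng.uniform(*config.baseline_log2_range, ng) * LN2
    sex_biased = rng.random(ng) < config.prop_sex_biased
    bs = np.where(sex_biased,
                  _signed_uniform(rng, *config.sex_effect_log2, ng), 0.0) * LN2
    phi = np.clip(rng.lognormal(config.dispersion_meanlog,
                                config.dispersion_sdlog, ng),
                  *config.dispersion_range)

    truth_frames = []
    mu = np.zeros((ng, len(samples)))
    for ci, (l1, l2) in enumerate(config.crosses):
        cross_id = _ROMAN[ci] if ci < len(_ROMAN) else f"C{ci + 1}"
        line_diff = rng.random(ng) < config.prop_line_diff
        ba = np.where(line_diff,
                      _signed_uniform(rng, *config.additive_effect_log2, ng), 0.0) * LN2
        discordant = line_diff & (rng.random(ng) < config.prop_line_discordant)
        # discordant genes: independent per-sex line effects
        ba_f = ba.copy()
        ba_m = ba.copy()
        alt = _signed_uniform(rng, *config.additive_effect_log2, ng) * LN2
        ba_m[discordant] = alt[discordant]
        # sex-specific dominance is only expressible on autosomes: males are
        # hemizygous on the X (no male heterozygote state) and the Y never
        # sees a heterozygote, so truth flags stay consistent with what the
        # design can show
        autosomal = chrom == "autosome"
        ssd = line_diff & ~discordant & autosomal & (rng.random(ng) < config.prop_ssd)
        delta_f = np.zeros(ng)
        delta_m = np.zeros(ng)
        conc = line_diff & ~discordant & ~ssd
        shared = _truncnorm(rng, config.delta_sd_concordant, config.delta_max, ng)
        delta_f[conc] = shared[conc]
        delta_m[conc] = shared[conc]
        df_ssd = _truncnorm(rng, config.delta_sd_ssd, config.delta_max, ng)
        dm_ssd = _truncnorm(rng, config.delta_sd_ssd, config.delta_max, ng)
        delta_f[ssd] = df_ssd[ssd]
        delta_m[ssd] = dm_ssd[ssd]
        delta_m[chrom == "X"] = np.nan  # never realized: male X is hemizygous
        has_poe = rng.random(ng) < config.prop_poe
        poe = np.where(has_poe, _signed_uniform(rng, *config.poe_ln, ng), 0.0)

        truth_frames.append(pd.DataFrame({
            "gene_id": gene_ids, "cross_id": cross_id, "chrom_class": chrom,
            "baseline_ln": base_ln, "sex_effect_ln": bs,
            "additive_f_ln": ba_f, "additive_m_ln": ba_m,
            "delta_f": delta_f, "delta_m": delta_m, "poe_ln": poe,
            "dispersion": phi,
            "sex_biased": sex_biased, "line_diff": line_diff,
            "line_discordant": discordant, "ssd": ssd, "has_poe": has_poe,
        }))

        # ---- expected means for this cross's samples ------------------
        sub = samples["cross"] == cross_id
        idx = np.flatnonzero(sub.to_numpy())
        is_x = chrom == "X"
        is_y = chrom == "Y"
        # per-sex parental means (sex code: female +1, male -1)
        for j in idx:
            row = samples.iloc[j]
            s = 1.0 if row["generated_sex"] == "female" else -1.0
            ba_s = ba_f if s > 0 else ba_m
            d_s = delta_f if s > 0 else delta_m
            base_s = np.exp(base_ln + s * bs / 2.0)
            m_low = base_s * np.exp(-ba_s / 2.0)   # line l1 homozygote
            m_high = base_s * np.exp(ba_s / 2.0)   # line l2 homozygote
            dam_is_l2 = row["dam"] == l2
            if row["homozygous"]:
                m = m_high if dam_is_l2 else m_low
                if is_y.any():
                    m = m.copy()
                    if s > 0:
                        m[is_y] = 0.01
            else:
                mid = 0.5 * (m_low + m_high)
                pcode = 1.0 if dam_is_l2 else -1.0
                m = mid * np.exp(d_s) * np.exp(pcode * poe / 2.0)
                if is_x.any() and s < 0:
                    # hemizygous males express the dam line's level
                    m = m.copy()
                    m[is_x] = (m_high if dam_is_l2 else m_low)[is_x]
                if is_y.any():
                    m = m.copy()
                    if s > 0:
                        m[is_y] = 0.01
                    else:
                        # Y is paternally inherited: follow the sire line
                        m[is_y] = (m_low if dam_is_l2 else m_high)[is_y]
            mu[:, j] = m

    # ---- library sizes and NB sampling --------------------------------
    lib = rng.lognormal(0.0, config.libsize_sdlog, len(samples))
    lib /= np.exp(np.mean(np.log(lib)))
    phi_all = np.concatenate([tf["dispersion"].to_numpy() for tf in truth_frames])
    # dispersion is per (gene, cross); expand to the sample grid
    phi_mat = np.zeros_like(mu)
    for ci in range(len(config.crosses)):
        cross_id = _ROMAN[ci] if ci < len(_ROMAN) else f"C{ci + 1}"
        cols = np.flatnonzero((samples["cross"] == cross_id).to_numpy())
        phi_mat[:, cols] = phi_all[ci * ng:(ci + 1) * ng, None]
    mu_scaled = mu * lib[None, :]
    shape = 1.0 / phi_mat
    lam = rng.gamma(shape, mu_scaled * phi_mat)
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(gene_ids, list(samples["sample_id"]), counts)
    truth = pd.concat(truth_frames, ignore_index=True)
    return cm, samples, genes, truth


def simulate_go_map(truth: pd.DataFrame, seed: int, n_terms: int = 40,
                    base_prob: float = 0.04, n_enriched: int = 2,
                    enriched_prob: float = 0.5) -> pd.DataFrame:
    """Toy GO annotation with terms planted as enriched among SSD genes.

    Every gene gets each of `n_terms` terms with probability `base_prob`;
    the first `n_enriched` terms additionally capture each SSD gene with
    probability `enriched_prob`, giving the over-representation stage a
    known positive control.
    """
    rng = np.random.default_rng(seed)
    genes = truth.drop_duplicates("gene_id")
    gene_ids = genes["gene_id"].to_numpy()
    is_ssd = truth.groupby("gene_id")["ssd"].any().loc[gene_ids].to_numpy()
    rows = []
    for t in range(n_terms):
        go_id = f"GO:{t + 1:07d}"
        hit = rng.random(len(gene_ids)) < base_prob
        if t < n_enriched:
            hit |= is_ssd & (rng.random(len(gene_ids)) < enriched_prob)
        for g in gene_ids[hit]:
            rows.append({"gene_id": g, "go_id": go_id})
    return pd.DataFrame(rows, columns=["gene_id", "go_id"])


def truth_recovery_report(truth: pd.DataFrame, results: pd.DataFrame,
                          q_cutoff: float = 0.05) -> dict:
    """Compare estimated dominance against the generating truth.

    Reports the signed bias and RMSE of the per-sex dominance estimates
    over genes where both truth and estimate are defined, and the
    confusion counts of sex-specific-dominance calls at the given q
    cutoff (truth positive = generated with delta_f != delta_m).
    """
    if "cross_id" not in results.columns:
        raise ValidationError("results table lacks cross_id")
    merged = results.merge(truth, on=["gene_id", "cross_id"], how="left",
                           suffixes=("", "_true"))
    if merged["delta_f_true"].isna().all() and len(merged):
        raise ValidationError("gene ids in results do not match the truth table")
    out: dict = {}
    for sex in ("f", "m"):
        est = merged[f"delta_{sex}"]
        tru = merged[f"delta_{sex}_true"]
        ok = est.notna() & tru.notna()
        err = (est[ok] - tru[ok]).to_numpy()
        out[f"bias_delta_{sex}"] = float(np.mean(err)) if len(err) else np.nan
        out[f"rmse_delta_{sex}"] = float(np.sqrt(np.mean(err ** 2))) if len(err) else np.nan
        out[f"n_delta_{sex}"] = int(ok.sum())
    called = merged["ssd"].fillna(False).astype(bool)
    true_pos = merged["ssd_true"].fillna(False).astype(bool)
    tested = merged["q_sexdom"].notna()
    tp = int((called & true_pos).sum())
    fp = int((called & ~true_pos).sum())
    fn = int((~called & true_pos & tested).sum())
    tn = int((~called & ~true_pos & tested).sum())
    out.update({"ssd_tp": tp, "ssd_fp": fp, "ssd_fn": fn, "ssd_tn": tn})
    out["ssd_sensitivity"] = tp / (tp + fn) if tp + fn else np.nan
    out["ssd_fdr"] = fp / (tp + fp) if tp + fp else np.nan
    return out
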