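"""Synthetic data with known ground truth for every pipeline input.

``generate_counts`` emulates the structure of the radiation study's
bulk RNA-seq design: two cell types (a cell line with 3 biological
replicates, primary macrophages from 4 donors), two doses (0 and 5 Gy),
gene and TE features, negative-binomial counts, planted differentially
expressed TE features, a low-expression noise regime, and per-donor
variability for the primary cells.

The generator plants structure on the *normalized* (log2 quantile) scale,
where the downstream procedures operate:

* every feature gets a target normalized mean ``m`` (log2 of cpm + 2) and a
  target coefficient of variation;
* in the well-measured ("signal") regime the target CV follows a linear
  trend ``cv = a + b*m`` — the regime in which the noise-floor detector's
  linear-reference assumption holds — and per-feature NB dispersion is
  calibrated to hit that target;
* the default library depth is derived so that the Poisson (shot-noise) CV
  floor crosses the linear trend exactly at the planted elbow: below it the
  CV~mean relation lifts away from the line, which is what the noise-floor
  detector is meant to find;
* planted "noise" features sit well below the elbow with additionally
  inflated dispersion.

A constant-dispersion mode (one NB dispersion per regime) is provided for
statistical benchmarking where a flat log-scale variance is wanted.

``generate_cq`` and ``generate_sequences`` produce qPCR tables and
FASTA/alignment fixtures with known folds, efficiencies, planted
complementary sites and conserved blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import CountMatrix, SampleDesign, build_design
from .qpcr import CqRecord

__all__ = [
    "SimConfig",
    "generate_counts",
    "generate_cq",
    "generate_titration",
    "generate_sequences",
    "de_benchmark_config",
    "null_config",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic count study.  Seed fully determines output."""

    # features
    n_genes: int = 17000
    te_families: tuple = (
        ("AluY", "Alu", "SINE", 700),
        ("L1HS", "L1", "LINE", 500),
        ("HERVK-int", "ERVK", "LTR", 500),
        ("HERV9-int", "ERV1", "LTR", 400),
        ("MER4D", "ERV1", "LTR", 300),
        ("MLT1B", "ERVL-MaLR", "LTR", 600),
    )
    # design: (cell_type, n_replicates); doses in Gy
    cell_types: tuple = (("THP1", 3), ("MDM", 4))
    doses: tuple = (0.0, 5.0)
    donor_cell_types: tuple = ("MDM",)
    donor_sd_log2: float = 0.2

    # planted CV ~ mean line (log2-normalized scale) and elbow
    elbow_log2: float = 3.0
    cv_intercept: float = 0.20
    cv_slope: float = -0.012
    cv_min: float = 0.02

    # regimes
    noise_fraction: float = 0.30
    noise_mean_range: tuple = (1.05, 1.7)
    noise_dispersion: float = 0.3
    signal_mean_offset: float = 2.7
    signal_mean_halfnormal_sd: float = 1.5
    signal_mean_cap: float = 11.0
    high_fraction: float = 0.03
    high_mean_range: tuple = (6.0, 11.0)

    # dispersion model: "cv_line" (calibrated to the planted CV line) or
    # "constant" (one dispersion per regime)
    dispersion_mode: str = "cv_line"
    constant_dispersion: float = 0.05

    # planted differential expression (applied to dose > 0 samples)
    n_de_te: int = 100
    de_fold: float = 4.0
    de_up_fraction: float = 0.9

    # sequencing depth; None derives the depth that puts the shot-noise
    # crossing at the planted elbow
    library_size: float | None = None
    library_sd_log: float = 0.1

    seed: int = 1

    @property
    def n_te(self) -> int:
        return sum(n for *_, n in self.te_families)

    @property
    def n_features(self) -> int:
        return self.n_genes + self.n_te

    def cv_line(self, m) -> np.ndarray:
        return np.maximum(self.cv_min, self.cv_intercept + self.cv_slope * np.asarray(m))

    def derived_library_size(self) -> float:
        if self.library_size is not None:
            return float(self.library_size)
        e = self.elbow_log2
        c = float(self.cv_line(e))
        counts_at_elbow = 1.0 / (LN2 * e * c) ** 2  # Poisson floor == line
        cpm_at_elbow = 2.0**e - 2.0
        return counts_at_elbow * 1e6 / cpm_at_elbow

    def validate(self) -> None:
        if not (0 <= self.noise_fraction < 1):
            raise ValueError("noise_fraction must be in [0, 1)")
        if self.noise_mean_range[0] <= 1.0 or self.signal_mean_offset <= 1.0:
            # log2(cpm + 2) is bounded below by 1 (cpm = 0)
            raise ValueError("normalized means must exceed 1.0 (the zero-count pedestal)")
        if not (0 <= self.high_fraction < 1):
            raise ValueError("high_fraction must be in [0, 1)")
        if self.noise_fraction + self.high_fraction >= 1:
            raise ValueError("regime fractions must leave room for signal features")
        if self.n_de_te > self.n_te:
            raise ValueError("more planted DE TEs than TE features")
        if not (0 <= self.de_up_fraction <= 1):
            raise ValueError("de_up_fraction must be in [0, 1]")
        if self.de_fold < 1:
            raise ValueError("de_fold must be >= 1")
        if self.dispersion_mode not in ("cv_line", "constant"):
            raise ValueError(f"unknown dispersion_mode: {self.dispersion_mode!r}")


def de_benchmark_config(**overrides) -> SimConfig:
    """Constant-dispersion benchmark: flat NB dispersion 0.05 in the signal
    regime, deeper libraries, no noise regime — for isolating the ANOVA/BH/
    Tukey/fold-change cascade's operating characteristics."""
    cfg = SimConfig(
        dispersion_mode="constant",
        constant_dispersion=0.05,
        noise_fraction=0.0,
        library_size=5e6,
    )
    return replace(cfg, **overrides)


def null_config(n_features: int = 5000, **overrides) -> SimConfig:
    """No planted effects at all (for false-positive-rate checks)."""
    n_te = 500
    fams = (("AluY", "Alu", "SINE", n_te),)
    cfg = SimConfig(
        n_genes=n_features - n_te,
        te_families=fams,
        n_de_te=0,
        dispersion_mode="constant",
        constant_dispersion=0.05,
        noise_fraction=0.0,
        library_size=5e6,
    )
    return replace(cfg, **overrides)


def _feature_ids(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    ids = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    is_te = [False] * cfg.n_genes
    for name, family, cls, n in cfg.te_families:
        for i in range(n):
            ids.append(f"{name}_{i:04d}:{family}:{cls}")
            is_te.append(True)
    return ids, np.array(is_te)


def _design_frame(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for cell_type, n_rep in cfg.cell_types:
        for dose in cfg.doses:
            for r in range(1, n_rep + 1):
                rep = f"d{r}" if cell_type in cfg.donor_cell_types else f"r{r}"
                rows.append(
                    {
                        "sample_id": f"{cell_type}_{dose:g}Gy_{rep}",
                        "cell_type": cell_type,
                        "dose_Gy": dose,
                        "replicate_id": rep,
                    }
                )
    return pd.DataFrame(rows)


def generate_counts(
    cfg: SimConfig, seed: int | None = None
) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """Simulate (CountMatrix, SampleDesign, truth table).

    The truth table has one row per feature: regime (noise/signal/high),
    is_te, is_noise_regime, is_de, direction, fold, and the target
    normalized mean.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ids, is_te = _feature_ids(cfg)
    n = cfg.n_features

    # ---- regime assignment ---------------------------------------------
    regime = np.full(n, "signal", dtype=object)
    gene_idx = np.flatnonzero(~is_te)
    n_high = int(round(cfg.high_fraction * n))
    high_idx = rng.choice(gene_idx, size=n_high, replace=False)
    regime[high_idx] = "high"
    remaining = np.flatnonzero(regime == "signal")
    n_noise = int(round(cfg.noise_fraction * n))
    noise_idx = rng.choice(remaining, size=n_noise, replace=False)
    regime[noise_idx] = "noise"

    # ---- planted differential expression (TEs in the signal regime) ----
    is_de = np.zeros(n, dtype=bool)
    direction = np.full(n, "", dtype=object)
    fold = np.ones(n)
    signal_te = np.flatnonzero((regime == "signal") & is_te)
    if cfg.n_de_te > 0 and cfg.de_fold > 1:  # fold 1 means nothing is DE
        if signal_te.size < cfg.n_de_te:
            raise ValueError("not enough signal-regime TEs for planted DE")
        de_idx = rng.choice(signal_te, size=cfg.n_de_te, replace=False)
        is_de[de_idx] = True
        n_up = int(round(cfg.de_up_fraction * cfg.n_de_te))
        up = rng.permutation(de_idx)[:n_up]
        direction[de_idx] = "down"
        direction[up] = "up"
        fold[is_de] = cfg.de_fold

    # ---- target normalized means ---------------------------------------
    m = np.empty(n)
    nz = regime == "noise"
    sg = regime == "signal"
    hg = regime == "high"
    m[nz] = rng.uniform(*cfg.noise_mean_range, size=nz.sum())
    m[sg] = np.minimum(
        cfg.signal_mean_cap,
        cfg.signal_mean_offset
        + np.abs(rng.normal(0, cfg.signal_mean_halfnormal_sd, size=sg.sum())),
    )
    m[hg] = rng.uniform(*cfg.high_mean_range, size=hg.sum())

    # cpm abundances; the high block absorbs the residual mass so that the
    # planted normalized means of the noise/signal regimes hold exactly
    p = 2.0**m - 2.0
    rest = p[~hg].sum()
    if hg.sum() > 0:
        if rest >= 0.95e6:
            raise ValueError("regime means leave no cpm mass for the high block")
        p[hg] *= (1e6 - rest) / p[hg].sum()
        m[hg] = np.log2(p[hg] + 2.0)
    else:
        p *= 1e6 / p.sum()
        m = np.log2(p + 2.0)

    # ---- samples --------------------------------------------------------
    design_df = _design_frame(cfg)
    design = build_design(design_df)
    samples = design.sample_ids
    L0 = cfg.derived_library_size()
    lib = L0 * np.exp(rng.normal(0, cfg.library_sd_log, size=len(samples)))
    lib_by_sample = dict(zip(samples, lib))

    # per-donor, per-feature effects (shared across doses within a donor)
    donor_eps: dict[tuple[str, str], np.ndarray] = {}
    tbl = design.table

    # ---- per-group expected cpm and dispersion -------------------------
    dose_treated = tbl["dose_Gy"].astype(float) > 0
    counts = np.empty((n, len(samples)), dtype=np.int64)

    # group base cpm (fold applied in irradiated samples)
    fold_vec_up = np.where(direction == "up", fold, 1.0)
    fold_vec_dn = np.where(direction == "down", fold, 1.0)

    for j, sid in enumerate(samples):
        row = tbl.loc[sid]
        treated = bool(dose_treated.loc[sid])
        q = p.copy()
        if treated:
            q = q * fold_vec_up / fold_vec_dn
        mj = np.log2(q + 2.0)

        # target log2-scale variance for this sample's feature set
        if cfg.dispersion_mode == "cv_line":
            target_sd = cfg.cv_line(mj) * mj
            target_var = target_sd**2
        else:
            phi_const = np.where(nz, cfg.noise_dispersion, cfg.constant_dispersion)

        # donor effect: shared across doses for the same donor
        if row["cell_type"] in cfg.donor_cell_types and cfg.donor_sd_log2 > 0:
            key = (row["cell_type"], row["replicate_id"])
            if key not in donor_eps:
                if cfg.dispersion_mode == "cv_line":
                    # donor variance is carved out of the target variance so
                    # the planted CV line still holds per group
                    base_m = np.log2(p + 2.0)
                    base_var = (cfg.cv_line(base_m) * base_m) ** 2
                    donor_sd = np.sqrt(
                        np.minimum(cfg.donor_sd_log2**2, 0.5 * base_var)
                    )
                else:
                    donor_sd = np.full(n, cfg.donor_sd_log2)
                donor_eps[key] = rng.normal(0, 1, size=n) * donor_sd
            eps = donor_eps[key]
            if cfg.dispersion_mode == "cv_line":
                base_m = np.log2(p + 2.0)
                base_var = (cfg.cv_line(base_m) * base_m) ** 2
                donor_var = np.minimum(cfg.donor_sd_log2**2, 0.5 * base_var)
                target_var = np.maximum(target_var - donor_var, 0.0)
        else:
            eps = 0.0

        Lj = lib_by_sample[sid]
        mu = q * 2.0**eps * (Lj / 1e6)

        if cfg.dispersion_mode == "cv_line":
            # convert residual log2-scale variance to NB dispersion
            sd_cpm = np.sqrt(target_var) * LN2 * (q + 2.0)
            sd_count = sd_cpm * (Lj / 1e6)
            mu_nominal = q * (Lj / 1e6)
            with np.errstate(divide="ignore", invalid="ignore"):
                phi = (sd_count**2 - mu_nominal) / mu_nominal**2
            phi = np.where(mu_nominal > 0, np.maximum(phi, 0.0), 0.0)
            phi[nz] = np.maximum(phi[nz], cfg.noise_dispersion)
        else:
            phi = phi_const

        has_od = phi > 0
        lam = mu.copy()
        if has_od.any():
            shape = 1.0 / phi[has_od]
            lam[has_od] = rng.gamma(shape, phi[has_od] * mu[has_od])
        counts[:, j] = rng.poisson(lam)

    cm = CountMatrix(pd.DataFrame(counts, index=ids, columns=samples))
    truth = pd.DataFrame(
        {
            "regime": regime,
            "is_te": is_te,
            "is_noise_regime": regime == "noise",
            "is_de": is_de,
            "direction": direction,
            "fold": fold,
            "target_mean_log2": m,
        },
        index=ids,
    )
    return cm, design, truth


# --------------------------------------------------------------------------
# qPCR fixtures
# --------------------------------------------------------------------------

def generate_cq(
    true_fold: float,
    efficiency: float = 1.0,
    noise_sd: float = 0.2,
    shared_noise_fraction: float = 0.7,
    replicates: int = 3,
    target: str = "target",
    reference: str = "reference",
    base_cq_target: float = 24.0,
    base_cq_reference: float = 16.0,
    seed: int = 0,
) -> list[CqRecord]:
    """Cq table for one target/reference pair across control and treated.

    Cq = base - log(quantity) / log(1 + E) + noise; the reference is
    generated with fold 1 so the ΔΔCt arithmetic should recover
    ``true_fold``.

    The per-well noise (total SD ``noise_sd``) is split into a component
    shared between the target and reference wells of the same replicate
    (template/loading error, ``shared_noise_fraction`` of the variance) and
    an independent well-specific remainder.  The shared part is exactly
    what normalizing against a reference gene cancels — modelling it is
    what makes ΔΔCt estimates tighter than naive independent-noise
    propagation would predict.
    """
    if not (0 < efficiency <= 1.2):
        raise ValueError("efficiency must be in (0, 1.2]")
    if not (0 <= shared_noise_fraction <= 1):
        raise ValueError("shared_noise_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[CqRecord] = []
    per_cycle = math.log(1.0 + efficiency)
    sd_shared = noise_sd * math.sqrt(shared_noise_fraction)
    sd_well = noise_sd * math.sqrt(1.0 - shared_noise_fraction)
    for condition, quantity in (("control", 1.0), ("treated", float(true_fold))):
        for r in range(replicates):
            shared = rng.normal(0, sd_shared) if sd_shared else 0.0
            for assay, base, q in (
                (target, base_cq_target, quantity),
                (reference, base_cq_reference, 1.0),
            ):
                cq = (
                    base
                    - math.log(q) / per_cycle
                    + shared
                    + (rng.normal(0, sd_well) if sd_well else 0.0)
                )
                records.append(
                    CqRecord(
                        sample_id=f"{condition}_s1",
                        condition=condition,
                        target=assay,
                        replicate=r + 1,
                        cq=float(cq),
                    )
                )
    return records


def generate_titration(
    efficiency: float = 1.0,
    amounts: tuple = (100.0, 25.0, 6.25, 1.5625, 0.390625),
    base_cq: float = 18.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Dilution series (amount, Cq) with Cq = base - log(amount)/log(1+E)."""
    if not (0 < efficiency <= 1.2):
        raise ValueError("efficiency must be in (0, 1.2]")
    rng = np.random.default_rng(seed)
    per_cycle = math.log(1.0 + efficiency)
    return [
        (a, base_cq - math.log(a) / per_cycle + (rng.normal(0, noise_sd) if noise_sd else 0.0))
        for a in amounts
    ]


# --------------------------------------------------------------------------
# sequence fixtures
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_sequences(
    guide: str,
    n_transcripts: int = 20,
    transcript_len: int = 1000,
    n_exact_sites: int = 3,
    n_one_mismatch_sites: int = 2,
    aln_n_seqs: int = 6,
    aln_len: int = 120,
    conserved_start: int = 40,
    conserved_len: int = 20,
    seed: int = 0,
) -> dict:
    """Random transcripts with planted guide-complementary sites, and a
    maximally-mixed alignment with one planted conserved block.

    Returns a dict with 'transcripts' [(id, seq)], 'alignment' [str], and a
    'manifest' recording planted coordinates."""
    from .seq_screen import reverse_complement

    rng = np.random.default_rng(seed)
    g = guide.upper()
    site = reverse_complement(g)
    L = len(site)
    site_arr = np.array(list(site))
    planted = []

    seqs = [np.array(list(_random_seq(rng, transcript_len))) for _ in range(n_transcripts)]

    # plant exact and one-mismatch sites, one per host transcript
    n_sites = n_exact_sites + n_one_mismatch_sites
    hosts = rng.choice(n_transcripts, size=n_sites, replace=False)
    planted_range = {}
    for i, host in enumerate(hosts):
        start = int(rng.integers(0, transcript_len - L + 1))
        insert = site_arr.copy()
        mm = 0
        if i >= n_exact_sites:
            pos = int(rng.integers(L))
            insert[pos] = rng.choice(_BASES[_BASES != insert[pos]])
            mm = 1
        seqs[host][start : start + L] = insert
        planted_range[int(host)] = (start, start + L)
        planted.append(
            {"seq_id": f"tx{host:03d}", "start": start, "end": start + L,
             "mismatches": mm}
        )

    # scrub chance near-complementary windows (within 2 mismatches) so the
    # manifest is exhaustive, never touching a planted site's bases
    for idx, arr in enumerate(seqs):
        p_lo, p_hi = planted_range.get(idx, (-1, -1))
        for _ in range(50):  # converges in a couple of passes
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            mm_counts = (windows != site_arr).sum(axis=1)
            offending = [
                s for s in np.flatnonzero(mm_counts <= 2)
                if not (s == p_lo and s + L == p_hi)
            ]
            if not offending:
                break
            for s in offending:
                positions = [
                    q for q in range(s, s + L) if not (p_lo <= q < p_hi)
                ]
                q = int(rng.choice(positions))
                arr[q] = rng.choice(_BASES[_BASES != arr[q]])
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not scrub accidental near-complementary sites")

    transcripts = [(f"tx{i:03d}", "".join(s)) for i, s in enumerate(seqs)]

    # alignment: iid-random columns except one conserved block
    block = _random_seq(rng, conserved_len)
    aln = []
    for _ in range(aln_n_seqs):
        s = list(_random_seq(rng, aln_len))
        s[conserved_start : conserved_start + conserved_len] = list(block)
        aln.append("".join(s))
    # force non-conserved columns to be mixed (>= 2 distinct residues)
    cols = [list(c) for c in zip(*aln)]
    for i, col in enumerate(cols):
        if conserved_start <= i < conserved_start + conserved_len:
            continue
        if len(set(col)) == 1:
            alt = str(rng.choice(_BASES[_BASES != col[0]]))
            col[int(rng.integers(len(col)))] = alt
    aln = ["".join(row) for row in zip(*cols)]

    planted.sort(key=lambda h: (h["seq_id"], h["start"]))
    return {
        "transcripts": transcripts,
        "alignment": aln,
        "manifest": {
            "guide": g,
            "sites": planted,
            "conserved_window": [conserved_start, conserved_start + conserved_len],
        },
    }
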