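"""Synthetic inputs with the statistical structure the analyses assume.

Every stage of the pipeline is exercisable without field or sequence
data: particle diameters follow a bounded power law, bottle oxygen
follows the two-point incubation model with Gaussian measurement noise,
alignment hit tables carry known true lineages with confounder hits
placed deliberately inside or outside the bit-score retention window,
and KO count tables are negative-binomial with planted fold changes.
Each generator is a pure function of its arguments and seed: the same
seed yields byte-identical output, and each generator draws from its own
stream split off a master seed so adding one generator never perturbs
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .taxonomy import RANKS, Taxonomy

__all__ = [
    "SimulationConfig",
    "gen_particle_sizes",
    "gen_bottles",
    "gen_hit_table",
    "gen_ko_table",
    "simulate_all",
    "DEFAULT_COMMUNITY",
]

# A small mixed plastic-biofilm community: lineages follow the
# domain;phylum;class;order;family;genus convention.
DEFAULT_COMMUNITY = {
    "Eukaryota;Bryozoa;Gymnolaemata;Cheilostomatida;Membraniporidae;Jellyella": 0.40,
    "Eukaryota;Retaria;Polycystinea;Spumellaria;Spongodiscidae;Spongaster": 0.10,
    "Bacteria;Cyanobacteria;Cyanophyceae;Oscillatoriales;Microcoleaceae;Phormidium": 0.20,
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae;Ruegeria": 0.15,
    "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae;Tenacibaculum": 0.10,
    "Bacteria;Proteobacteria;Alphaproteobacteria;Caulobacterales;Hyphomonadaceae;Hyphomonas": 0.05,
}


@dataclass
class SimulationConfig:
    """Defaults describing the study conditions the generators emulate.

    Particle sizes follow the steady-state fragmentation exponent 3 over
    the trawl-resolvable 0.3–30 mm range; bottle truth is a net
    autotrophic community (NCP 10, R 5 µmol O2/L/day) measured with
    ~1 µmol/L Winkler noise over 24 h; the KO comparison mirrors a
    12-vs-17-sample design at ~216,000 KO-assigned reads per library
    with 10% of KOs planted at a 16-fold (log2FC = 4) difference.
    """

    seed: int = 0
    # particles
    n_particles: int = 5000
    size_exponent: float = 3.0
    d_min: float = 0.3
    d_max: float = 30.0
    # bottles
    ncp: float = 10.0
    r: float = 5.0
    baseline_o2: float = 210.0
    noise_sd: float = 1.0
    n_per_treatment: int = 8
    duration_h: float = 24.0
    # community / hit tables
    community: dict = field(default_factory=lambda: dict(DEFAULT_COMMUNITY))
    reads_per_sample: int = 1000
    identity_noise: float = 2.0
    # KO tables
    n_kos: int = 2000
    group_sizes: tuple = (12, 17)
    planted_fraction: float = 0.1
    planted_log2fc: float = 4.0
    nb_dispersion: float = 0.1
    library_size: int = 216_000


def gen_particle_sizes(n: int, exponent: float = 3.0, d_min: float = 0.3,
                       d_max: float = 30.0, seed: int = 0) -> np.ndarray:
    """Diameters (mm) from the bounded power-law density ∝ d^-exponent.

    Inverse-CDF sampling on [d_min, d_max]; the exponent-1 case uses the
    log-uniform closed form.
    """
    if not (0 < d_min <= d_max):
        raise ValueError("need 0 < d_min <= d_max")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    if d_min == d_max:
        return np.full(n, d_min)
    if np.isclose(exponent, 1.0):
        return d_min * (d_max / d_min) ** u
    a = 1.0 - exponent
    return (d_min**a + u * (d_max**a - d_min**a)) ** (1.0 / a)


def bounded_powerlaw_cdf(d, exponent: float, d_min: float, d_max: float):
    """Analytic CDF of the bounded power law (oracle for the sampler)."""
    d = np.asarray(d, dtype=float)
    if np.isclose(exponent, 1.0):
        return np.log(d / d_min) / np.log(d_max / d_min)
    a = 1.0 - exponent
    return (d**a - d_min**a) / (d_max**a - d_min**a)


def gen_bottles(ncp: float = 10.0, r: float = 5.0, baseline: float = 210.0,
                n_per_treatment: int = 8, noise_sd: float = 1.0,
                duration_h: float = 24.0, seed: int = 0,
                experiment_id: str = "exp", station: str = "S1",
                size_class: str = "seawater", bottle_volume_L: float = 0.125,
                particle_volume_L: float = 0.0) -> pd.DataFrame:
    """Bottle-incubation oxygen table under the two-point rate model.

    t0 bottles sit at the baseline concentration; light bottles gain
    NCP x (duration/24) and dark bottles lose R x (duration/24), all with
    additive Gaussian measurement noise.  Negative concentrations are
    clipped at zero with a warning.
    """
    if n_per_treatment < 1:
        raise ValueError("n_per_treatment must be >= 1")
    rng = np.random.default_rng(seed)
    frac = duration_h / 24.0
    means = {"t0": baseline, "light": baseline + ncp * frac, "dark": baseline - r * frac}
    rows = []
    for treatment, mu in means.items():
        vals = mu + rng.normal(0.0, noise_sd, n_per_treatment)
        if np.any(vals < 0):
            import warnings

            warnings.warn("negative generated O2 clipped at 0", stacklevel=2)
            vals = np.clip(vals, 0.0, None)
        for v in vals:
            rows.append(
                {
                    "experiment_id": experiment_id,
                    "station": station,
                    "treatment": treatment,
                    "size_class": size_class,
                    "o2_umol_per_L": v,
                    "bottle_volume_L": bottle_volume_L,
                    "particle_volume_L": particle_volume_L,
                    "duration_h": duration_h,
                }
            )
    return pd.DataFrame(rows)


def _mutate_lineage(lineage: tuple, rank_idx: int, tag: str) -> tuple:
    """Sister lineage differing from ``lineage`` at ``rank_idx`` and below."""
    out = list(lineage)
    for i in range(rank_idx, len(out)):
        out[i] = f"{out[i]}_{tag}"
    return tuple(out)


def gen_hit_table(community: dict | None = None, reads_per_sample: int = 1000,
                  identity_noise: float = 2.0, seed: int = 0,
                  samples: tuple = ("sample_1",),
                  confounder_rank: str = "genus",
                  p_confounder_in_window: float = 0.3,
                  p_confounder_out_window: float = 0.3,
                  window: float = 0.01):
    """Synthetic alignment hit table with known LCA truth.

    Each read originates from one community clade and always hits its
    true subject with the best bit score.  With probability
    ``p_confounder_in_window`` a confounder subject — identical lineage
    except at ``confounder_rank`` and below — is hit just inside the
    bit-score retention window, making the truthful assignment the rank
    above ``confounder_rank``.  With probability
    ``p_confounder_out_window`` a confounder lands just outside the
    window (retention must ignore it).  Offsets are constructed, not
    sampled, so the window boundary is exercised by design.

    Returns ``(hits, taxonomy, truth)``; truth records each read's
    generating lineage truncated at its deepest unambiguous rank.
    """
    community = dict(DEFAULT_COMMUNITY) if community is None else community
    rng = np.random.default_rng(seed)
    rank_idx = RANKS.index(confounder_rank)

    clades = list(community)
    probs = np.array([community[c] for c in clades], dtype=float)
    probs = probs / probs.sum()

    lineages: dict[str, tuple] = {}
    for i, clade in enumerate(clades):
        lin = tuple(clade.split(";"))
        lineages[f"ACC{i:03d}"] = lin
        lineages[f"ACC{i:03d}_SIS"] = _mutate_lineage(lin, rank_idx, "sister")
    taxonomy = Taxonomy(lineages=dict(lineages))

    hit_rows, truth_rows = [], []
    for sample in samples:
        choice = rng.choice(len(clades), size=reads_per_sample, p=probs)
        for j, ci in enumerate(choice):
            read_id = f"{sample}_read{j:06d}"
            acc = f"ACC{ci:03d}"
            true_lineage = lineages[acc]
            best_bit = float(rng.uniform(200, 600))
            pident = float(np.clip(100.0 - abs(rng.normal(0, identity_noise)), 70, 100))
            length = int(rng.integers(120, 250))
            hit_rows.append(
                {"qseqid": read_id, "sseqid": acc, "pident": pident,
                 "length": length, "bitscore": round(best_bit, 1), "sample": sample}
            )
            u = rng.random()
            if u < p_confounder_in_window:
                # just inside the window: offset at half the window width
                bit = round(best_bit * (1.0 - window / 2.0), 1)
                truth_depth = rank_idx
                hit_rows.append(
                    {"qseqid": read_id, "sseqid": f"{acc}_SIS", "pident": pident - 1,
                     "length": length, "bitscore": bit, "sample": sample}
                )
            elif u < p_confounder_in_window + p_confounder_out_window:
                # just outside: twice the window width below the best
                bit = round(best_bit * (1.0 - 2.0 * window), 1)
                truth_depth = len(true_lineage)
                hit_rows.append(
                    {"qseqid": read_id, "sseqid": f"{acc}_SIS", "pident": pident - 2,
                     "length": length, "bitscore": bit, "sample": sample}
                )
            else:
                truth_depth = len(true_lineage)
            truth_rows.append(
                {
                    "read_id": read_id,
                    "sample": sample,
                    "true_lineage": ";".join(true_lineage[:truth_depth]),
                    "true_rank": RANKS[truth_depth - 1],
                    "source_clade": clades[ci],
                }
            )
    hits = pd.DataFrame(hit_rows)
    truth = pd.DataFrame(truth_rows)
    return hits, taxonomy, truth


def gen_ko_table(n_kos: int = 2000, group_sizes: tuple = (12, 17),
                 planted_fraction: float = 0.1, planted_log2fc: float = 4.0,
                 nb_dispersion: float = 0.1, library_size: int = 216_000,
                 seed: int = 0):
    """Negative-binomial KO × sample count table with planted fold changes.

    A fraction of KOs gets a group-A mean raised by 2^log2fc; base
    relative abundances follow a log-normal across KOs; per-sample
    library sizes scale all means.  ``nb_dispersion`` is the NB shape
    parameter alpha (variance mu + alpha mu^2); alpha → 0 degenerates to
    Poisson.

    Returns ``(counts, groups, truth_flags)`` where groups maps sample →
    {"plastic", "picoplankton"} and truth_flags is a boolean Series over
    KOs (True = planted, enriched in the plastic group).
    """
    if min(group_sizes) < 2:
        raise ValueError("need at least two samples per group")
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_a, n_b = group_sizes
    samples = [f"plastic_{i + 1}" for i in range(n_a)] + [
        f"pico_{i + 1}" for i in range(n_b)
    ]
    groups = {s: ("plastic" if s.startswith("plastic") else "picoplankton") for s in samples}

    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_kos)
    base = base / base.sum()
    n_planted = int(round(planted_fraction * n_kos))
    planted = np.zeros(n_kos, dtype=bool)
    planted[rng.choice(n_kos, size=n_planted, replace=False)] = True

    fold = 2.0**planted_log2fc
    mean_a = base * np.where(planted, fold, 1.0)
    mean_b = base.copy()

    def draw(mean_rel, n_samples):
        # per-sample depth jitter (+-10%) then NB draws around depth x relative mean
        depths = library_size * rng.uniform(0.9, 1.1, size=n_samples)
        mu = np.outer(mean_rel, depths)
        if nb_dispersion <= 0:
            return rng.poisson(mu)
        shape = 1.0 / nb_dispersion
        p = shape / (shape + mu)
        return rng.negative_binomial(shape, p)

    counts = np.hstack([draw(mean_a, n_a), draw(mean_b, n_b)])
    ko_ids = [f"K{i + 1:05d}" for i in range(n_kos)]
    table = pd.DataFrame(counts, index=ko_ids, columns=samples)
    flags = pd.Series(planted, index=ko_ids, name="planted")
    return table, groups, flags


def simulate_all(config: SimulationConfig | None = None, out_dir=None) -> dict:
    """Generate every fixture from one config; optionally write TSVs.

    Returns a dict of in-memory objects; with ``out_dir`` also writes
    particle, bottle, hit, taxonomy, KO and truth tables plus a manifest
    recording the seed and config.
    """
    import hashlib
    import json
    from pathlib import Path

    cfg = config or SimulationConfig()
    seeds = {name: int(np.random.SeedSequence((cfg.seed, i)).generate_state(1)[0] % 2**31)
             for i, name in enumerate(["particles", "bottles", "hits", "kos"])}

    diameters = gen_particle_sizes(cfg.n_particles, cfg.size_exponent,
                                   cfg.d_min, cfg.d_max, seed=seeds["particles"])
    bottles = gen_bottles(cfg.ncp, cfg.r, cfg.baseline_o2, cfg.n_per_treatment,
                          cfg.noise_sd, cfg.duration_h, seed=seeds["bottles"])
    hits, taxonomy, truth = gen_hit_table(cfg.community, cfg.reads_per_sample,
                                          cfg.identity_noise, seed=seeds["hits"])
    ko_counts, groups, flags = gen_ko_table(
        cfg.n_kos, cfg.group_sizes, cfg.planted_fraction, cfg.planted_log2fc,
        cfg.nb_dispersion, cfg.library_size, seed=seeds["kos"],
    )
    result = {
        "diameters": diameters,
        "bottles": bottles,
        "hits": hits,
        "taxonomy": taxonomy,
        "lca_truth": truth,
        "ko_counts": ko_counts,
        "ko_groups": groups,
        "ko_truth": flags,
        "config": cfg,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        particles = pd.DataFrame(
            {
                "particle_id": [f"P{i:05d}" for i in range(len(diameters))],
                "station": "SYN1",
                "size_class": pd.cut(
                    diameters, [0, 2, 5, np.inf],
                    labels=["0.2-2mm", ">2-5mm", ">5mm"],
                ),
                "diameter_mm": diameters,
            }
        )
        particles.to_csv(out / "particles.tsv", sep="\t", index=False)
        bottles.to_csv(out / "bottles.tsv", sep="\t", index=False)
        hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        taxonomy.to_tsv(out / "taxonomy.tsv")
        truth.to_csv(out / "lca_truth.tsv", sep="\t", index=False)
        ko_counts.to_csv(out / "ko_counts.tsv", sep="\t")
        pd.Series(groups, name="group").rename_axis("sample").to_csv(
            out / "ko_groups.tsv", sep="\t"
        )
        flags.rename_axis("ko").to_csv(out / "ko_truth.tsv", sep="\t")
        cfg_dict = asdict(cfg)
        cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
        manifest = {
            "seed": cfg.seed,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
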