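"""Synthetic metatranscriptome bundles with planted ground truth.

The generator emulates the statistical structure of a whole-body
worker/soldier termite metatranscriptome at desk scale: a taxonomy
containing the host clade (Blattodea) and symbiont clade (Metamonada) with
its flagellate orders and genera, nucleotide-similarity hit tables whose
structure drives the source classifier, negative-binomial count matrices
with planted caste fold changes, and latent-factor host-flagellate
expression coupling that is stronger in workers than in soldiers.

Mean model (log2 scale) for transcript g in sample j:

    log2 mu_gj = base_g + soldier_j * lfc_g
               + load_g * (gamma_caste(j) * z_j + delta * w_j)   (coupled)
               + load_g * (gamma_caste(j) * v_j + delta * v2_j)  (flagellate)
               + pload_g * u_{p(g), j}                           (host/unclear)

where z_j is the caste-asymmetric host-symbiont coupling factor
(gamma_worker > gamma_soldier) shared by the planted coupled pairs,
(v_j, v2_j) the latent flagellate-load factors tracked by the remaining
flagellate transcripts — like the coupling, far more tightly in workers
than in soldiers — and u_{p,j} broad caste-independent expression
programs covering host and unclear transcripts (emulating the pervasive
correlated variation of whole-body RNA-seq, e.g. tissue composition).
Every latent multiplicative factor is centered within caste and
normalized to within-caste mean one on the count scale, so transcripts
with planted_lfc = 0 are exactly null for the caste contrast.  Counts
are NB with Var = mu + phi * mu^2, phi log-normal around the configured
dispersion; samples are scaled to library sizes drawn from
``libsize_range``.

Fixing the seed makes every bundle byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CountMatrix, SOLDIER, WORKER
from .source_classifier import FLAGELLATE, TERMITE, UNCLEAR
from .taxonomy import TaxonNode, TaxonomyTable

# ---------------------------------------------------------------------------
# taxonomy constants

BLATTODEA = 85823
METAMONADA = 2611341

# (taxid, parent, rank, name) — host clade, symbiont orders/genera/species,
# and fungal/bacterial outgroups used for decoy hits.
_TAXA: list[tuple[int, int, str, str]] = [
    (1, 1, "no rank", "root"),
    # host side
    (BLATTODEA, 1, "order", "Blattodea"),
    (1000101, BLATTODEA, "family", "Kalotermitidae"),
    (1000102, 1000101, "genus", "Neotermes"),
    (1000103, 1000102, "species", "Neotermes binovatus"),
    (1000104, 1000102, "species", "Neotermes castaneus"),
    (1000105, BLATTODEA, "family", "Rhinotermitidae"),
    (1000106, 1000105, "genus", "Coptotermes"),
    (1000107, 1000106, "species", "Coptotermes formosanus"),
    # symbiont side
    (METAMONADA, 1, "clade", "Metamonada"),
    (1000201, METAMONADA, "order", "Cristamonadida"),
    (1000202, 1000201, "genus", "Devescovina"),
    (1000203, 1000202, "species", "Devescovina lemniscata"),
    (1000204, 1000202, "species", "Devescovina sp. Nb-1"),
    (1000205, 1000201, "genus", "Calonympha"),
    (1000206, 1000205, "species", "Calonympha grassii"),
    (1000211, METAMONADA, "order", "Oxymonadida"),
    (1000212, 1000211, "genus", "Oxymonas"),
    (1000213, 1000212, "species", "Oxymonas dimorpha"),
    (1000214, 1000212, "species", "Oxymonas sp. Nb-2"),
    (1000215, 1000211, "genus", "Blattamonas"),
    (1000216, 1000215, "species", "Blattamonas nauphoetae"),
    (1000217, 1000211, "genus", "Streblomastix"),
    (1000218, 1000217, "species", "Streblomastix strix"),
    (1000221, METAMONADA, "order", "Trichomonadida"),
    (1000222, 1000221, "genus", "Trichomonas"),
    (1000223, 1000222, "species", "Trichomonas vaginalis"),
    (1000224, 1000221, "genus", "Pentatrichomonas"),
    (1000225, 1000224, "species", "Pentatrichomonas hominis"),
    (1000231, METAMONADA, "order", "Tritrichomonadida"),
    (1000232, 1000231, "genus", "Tritrichomonas"),
    (1000233, 1000232, "species", "Tritrichomonas foetus"),
    (1000234, 1000231, "genus", "Simplicimonas"),
    (1000235, 1000234, "species", "Simplicimonas similis"),
    # outgroups for decoys
    (4751, 1, "kingdom", "Fungi"),
    (1000301, 4751, "genus", "Aspergillus"),
    (1000302, 1000301, "species", "Aspergillus nidulans"),
    (2, 1, "superkingdom", "Bacteria"),
    (1000311, 2, "genus", "Bacillus"),
    (1000312, 1000311, "species", "Bacillus subtilis"),
]

ORDERS = ("Cristamonadida", "Oxymonadida", "Trichomonadida",
          "Tritrichomonadida")
# order name -> species taxids grouped by genus
_ORDER_SPECIES: dict[str, list[list[int]]] = {
    "Cristamonadida": [[1000203, 1000204], [1000206]],
    "Oxymonadida": [[1000213, 1000214], [1000216], [1000218]],
    "Trichomonadida": [[1000223], [1000225]],
    "Tritrichomonadida": [[1000233], [1000235]],
}
_HOST_SPECIES = [1000103, 1000104, 1000107]
_DECOY_SPECIES = [1000302, 1000312]

GENE_CLASSES = ("18S rRNA", "actin", "alpha tubulin", "beta tubulin",
                "EF1a", "GAPDH", "others")
_GENE_PROBS = (0.055, 0.356, 0.115, 0.129, 0.062, 0.048, 0.235)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic bundle.

    Defaults mirror the emulated study: 10 workers + 10 soldiers, a
    desk-scale transcriptome of 600 transcripts, NB dispersion 0.1,
    planted two-fold (|log2FC| = 2) caste effects on 15% of transcripts,
    and host-symbiont coupling much stronger in workers
    (gamma_w = 0.8) than soldiers (gamma_s = 0.1).
    """

    n_worker: int = 10
    n_soldier: int = 10
    n_termite: int = 380
    n_flagellate: int = 100
    n_unclear: int = 120
    frac_de: float = 0.15
    lfc_mean: float = 2.0
    lfc_sd: float = 0.25
    dispersion: float = 0.1
    libsize_range: tuple[int, int] = (800_000, 1_200_000)
    coupling_worker: float = 0.8
    coupling_soldier: float = 0.1
    n_coupled_pairs: int = 20
    identity_ranges: dict = field(default_factory=lambda: {
        "genus": (90.5, 99.5),    # strict >90 per the genus consensus rule
        "order": (81.0, 90.0),    # >80 but not all >90
        "source": (81.0, 95.0),   # mixed orders: source-level only
        "host": (85.0, 99.0),
    })
    decoy_rate: float = 0.34      # fraction of unclear pool given decoy hits
    seed: int = 0
    # covariance structure beyond the coupling factor (see module docstring)
    coupled_load_range: tuple[float, float] = (3.0, 3.5)
    coabundance_strength: float = 0.20   # delta: caste-independent clique factor
    program_strength: float = 0.85       # pload scale for expression programs
    n_host_programs: int = 3
    # flagellate resolution-tier fractions (genus, order, source-only)
    tier_fracs: tuple[float, float, float] = (0.10, 0.25, 0.65)
    frac_low_expressed: float = 0.08
    # caste effects on flagellate transcripts are off by default: the
    # emulated study found no significant flagellate abundance
    # differences between castes, and flagellate expression is dominated
    # by the latent flagellate-load factors instead
    de_on_flagellates: bool = False

    def __post_init__(self):
        for name in ("n_worker", "n_soldier", "n_termite", "n_flagellate",
                     "n_unclear", "n_coupled_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must be in [0, 1]")
        if not self.coupling_worker >= self.coupling_soldier >= 0:
            raise ValueError("require coupling_worker >= coupling_soldier >= 0")
        if self.libsize_range[0] > self.libsize_range[1]:
            raise ValueError("libsize_range must be ordered")

    @property
    def n_transcripts(self) -> int:
        return self.n_termite + self.n_flagellate + self.n_unclear


@dataclass
class SyntheticTruth:
    """Planted ground truth for one bundle."""

    transcripts: list[str]
    samples: list[str]
    castes: dict[str, str]
    source: dict[str, str]                 # termite | flagellate | unclear
    order: dict[str, str | None]           # order name, flagellates only
    genus: dict[str, str | None]
    gene_class: dict[str, str]             # flagellates only
    planted_lfc: dict[str, float]          # 0.0 for non-DE transcripts
    coupled_pairs: list[tuple[str, str]]   # (flagellate, other)
    module_membership: dict[str, str]      # program / coupled label
    unclear_flavor: dict[str, str]         # nohit | subthreshold | decoy


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def generate_taxonomy(config: SimConfig | None = None) -> TaxonomyTable:
    """The bundled taxonomy: Blattodea, Metamonada with its four flagellate
    orders and their genera, plus fungal and bacterial outgroups."""
    return TaxonomyTable(TaxonNode(*row) for row in _TAXA)


def simulate_truth(config: SimConfig) -> SyntheticTruth:
    rng = _rng(config, 1)
    n = config.n_transcripts
    transcripts = [f"tx{i:04d}" for i in range(n)]
    samples = [f"W{i + 1:02d}" for i in range(config.n_worker)] + \
              [f"S{i + 1:02d}" for i in range(config.n_soldier)]
    castes = {s: (WORKER if s.startswith("W") else SOLDIER) for s in samples}

    labels = np.array([TERMITE] * config.n_termite
                      + [FLAGELLATE] * config.n_flagellate
                      + [UNCLEAR] * config.n_unclear)
    rng.shuffle(labels)
    source = dict(zip(transcripts, labels))
    flag_ids = [t for t in transcripts if source[t] == FLAGELLATE]
    other_ids = [t for t in transcripts if source[t] != FLAGELLATE]

    # resolution tier and taxonomic assignment of flagellates
    order: dict[str, str | None] = {}
    genus: dict[str, str | None] = {}
    gene_class: dict[str, str] = {}
    tier_draw = rng.choice(3, size=len(flag_ids), p=list(config.tier_fracs))
    order_draw = rng.choice(len(ORDERS), size=len(flag_ids),
                            p=(0.70, 0.10, 0.10, 0.10))
    gene_draw = rng.choice(len(GENE_CLASSES), size=len(flag_ids),
                           p=_GENE_PROBS)
    tax = generate_taxonomy(config)
    for t, tier, oi, gi in zip(flag_ids, tier_draw, order_draw, gene_draw):
        gene_class[t] = GENE_CLASSES[gi]
        if tier == 2:                      # source-level only
            order[t] = None
            genus[t] = None
        else:
            oname = ORDERS[oi]
            order[t] = oname
            if tier == 0:                  # genus-resolved
                genus_group = _ORDER_SPECIES[oname][
                    rng.integers(len(_ORDER_SPECIES[oname]))]
                genus_taxid = tax.nodes[genus_group[0]].parent
                genus[t] = tax.name(genus_taxid)
            else:
                genus[t] = None

    # planted caste effects (soldier vs worker), random sign
    planted_lfc = {t: 0.0 for t in transcripts}
    de_pool = transcripts if config.de_on_flagellates else other_ids
    n_de = min(int(round(config.frac_de * n)), len(de_pool))
    de_ids = list(rng.choice(de_pool, size=n_de, replace=False))
    for t in de_ids:
        mag = rng.normal(config.lfc_mean, config.lfc_sd)
        planted_lfc[t] = float(mag * rng.choice([-1.0, 1.0]))

    # coupled pairs: flagellate member x non-flagellate member, all non-DE
    flag_pool = [t for t in flag_ids if planted_lfc[t] == 0.0]
    other_pool = [t for t in other_ids if planted_lfc[t] == 0.0]
    if config.n_coupled_pairs > min(len(flag_pool), len(other_pool)):
        raise ValueError("n_coupled_pairs exceeds available pairs")
    cf = list(rng.choice(flag_pool, size=config.n_coupled_pairs,
                         replace=False))
    co = list(rng.choice(other_pool, size=config.n_coupled_pairs,
                         replace=False))
    coupled_pairs = list(zip(cf, co))

    coupled = set(cf) | set(co)
    module_membership = {}
    host_program = {
        t: f"program{rng.integers(config.n_host_programs) + 1}"
        for t in other_ids}
    for t in transcripts:
        if t in coupled:
            module_membership[t] = "coupled"
        elif source[t] == FLAGELLATE:
            module_membership[t] = "flagellate-program"
        else:
            module_membership[t] = host_program[t]

    # unclear flavors
    unclear_ids = [t for t in transcripts if source[t] == UNCLEAR]
    unclear_flavor = {}
    n_decoy = int(round(config.decoy_rate * len(unclear_ids)))
    decoys = set(rng.choice(unclear_ids, size=n_decoy, replace=False)) \
        if n_decoy else set()
    rest = [t for t in unclear_ids if t not in decoys]
    for i, t in enumerate(rest):
        unclear_flavor[t] = "nohit" if i % 2 == 0 else "subthreshold"
    for t in decoys:
        unclear_flavor[t] = "decoy"

    return SyntheticTruth(transcripts, samples, castes, source, order, genus,
                          gene_class, planted_lfc, coupled_pairs,
                          module_membership, unclear_flavor)


def simulate_counts(truth: SyntheticTruth, config: SimConfig) -> CountMatrix:
    rng = _rng(config, 2)
    transcripts, samples = truth.transcripts, truth.samples
    n, m = len(transcripts), len(samples)
    soldier = np.array(
        [truth.castes[s] == SOLDIER for s in samples], dtype=float)
    coupled = {t for pair in truth.coupled_pairs for t in pair}

    # baseline log2 abundance; planted-DE and coupled transcripts are kept
    # moderately-to-highly expressed so the planted signal survives the
    # CPM filter; a small fraction of the remainder is low-expressed to
    # exercise it.
    base = rng.normal(6.5, 1.2, size=n)
    lfc = np.array([truth.planted_lfc[t] for t in transcripts])
    is_special = np.array([t in coupled or truth.planted_lfc[t] != 0.0
                           for t in transcripts], dtype=bool)
    base[is_special] = np.clip(rng.normal(7.0, 1.0, size=int(
        is_special.sum())), 5.0, 11.0)
    eligible = np.flatnonzero(~is_special)
    n_low = int(round(config.frac_low_expressed * n))
    low = rng.choice(eligible, size=min(n_low, eligible.size), replace=False)
    # ~2^11 below the typical transcript: sub-CPM-1, dropped by the filter
    base[low] = rng.normal(-5.0, 1.0, size=low.size)

    # latent factors (per sample), centered within caste so that latent
    # variation is orthogonal to the caste contrast: transcripts with
    # planted_lfc = 0 are exactly null for the caste comparison
    def caste_centered(x: np.ndarray) -> np.ndarray:
        out = x.copy()
        for grp in (soldier > 0, soldier == 0):
            if grp.any():
                out[grp] -= out[grp].mean()
        return out

    z = caste_centered(rng.normal(size=m))        # caste-asymmetric coupling
    w = caste_centered(rng.normal(size=m))        # coupled co-abundance
    v = caste_centered(rng.normal(size=m))        # flagellate-load factor
    v2 = caste_centered(rng.normal(size=m))       # flagellate co-abundance
    programs = sorted({p for p in truth.module_membership.values()
                       if p != "coupled"})
    u = {p: caste_centered(rng.normal(size=m)) for p in programs}

    gamma = np.where(soldier > 0, config.coupling_soldier,
                     config.coupling_worker)
    load = rng.uniform(*config.coupled_load_range, size=n)
    pload = config.program_strength * rng.uniform(0.8, 1.2, size=n)

    log2mu = np.tile(base[:, None], (1, m)) + lfc[:, None] * soldier[None, :]

    def unit_mean_factor(log2f: np.ndarray) -> np.ndarray:
        """Normalize a multiplicative factor to within-caste mean one on
        the count scale, so latent variation cannot masquerade as a caste
        mean difference (a variance difference otherwise inflates the
        arithmetic mean — a Jensen effect)."""
        f = 2.0 ** log2f
        for grp in (soldier > 0, soldier == 0):
            if grp.any():
                f[grp] /= f[grp].mean()
        return np.log2(f)

    for i, t in enumerate(transcripts):
        mod = truth.module_membership[t]
        if mod == "coupled":
            log2mu[i] += unit_mean_factor(load[i] * (
                gamma * z + config.coabundance_strength * w))
        elif mod == "flagellate-program":
            # non-coupled flagellate transcripts track the latent
            # flagellate load, which (like the coupling) co-varies far
            # more tightly in workers than in soldiers
            log2mu[i] += unit_mean_factor(load[i] * (
                gamma * v + config.coabundance_strength * v2))
        else:
            log2mu[i] += unit_mean_factor(pload[i] * u[mod])

    mu = 2.0 ** log2mu
    libsizes = rng.uniform(config.libsize_range[0],
                           config.libsize_range[1], size=m)
    if n > 0:
        mu = mu / mu.sum(axis=0, keepdims=True) * libsizes[None, :]

    # per-transcript dispersion, log-normal around the configured value
    if config.dispersion > 0:
        phi = config.dispersion * np.exp(rng.normal(0.0, 0.25, size=n))
    else:
        phi = np.zeros(n)
    counts = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        if phi[i] < 1e-8:
            counts[i] = rng.poisson(mu[i])
        else:
            r = 1.0 / phi[i]
            counts[i] = rng.negative_binomial(r, r / (r + mu[i]))

    df = pd.DataFrame(counts, index=transcripts, columns=samples)
    castes = pd.Series({s: truth.castes[s] for s in samples})
    return CountMatrix(df, castes)


# ---------------------------------------------------------------------------
# hit-table simulation


def _emit_hit(rows: list, qseqid: str, taxid: int, pident: float,
              length: int, qstart: int, rng: np.random.Generator,
              evalue: float | None = None) -> None:
    length = max(int(length), 30)
    mismatch = int(round(length * (1 - pident / 100)))
    sstart = int(rng.integers(1, 500))
    bitscore = round(1.8 * length * pident / 100 + rng.uniform(0, 0.5), 1)
    if evalue is None:
        evalue = 10.0 ** (-float(rng.uniform(20, 120)))
    rows.append((qseqid, f"subj{taxid}_{len(rows)}", round(pident, 2),
                 length, mismatch, min(int(rng.integers(0, 4)), mismatch),
                 qstart, qstart + length - 1, sstart, sstart + length - 1,
                 evalue, bitscore, taxid))


def simulate_hits(truth: SyntheticTruth, tax: TaxonomyTable,
                  config: SimConfig) -> pd.DataFrame:
    """Hit table (13 tabular columns) realizing each transcript's truth.

    Termite transcripts get host-clade best hits; flagellate transcripts
    get five (or six) Metamonada hits whose identities and taxa encode the
    planted resolution tier; unclear transcripts get no hits, hits above
    the E-value cutoff, or decoy cross-clade conflicts.
    """
    rng = _rng(config, 3)
    rows: list[tuple] = []
    for t in truth.transcripts:
        src = truth.source[t]
        if src == TERMITE:
            L = int(rng.integers(400, 1500))
            pid = rng.uniform(*config.identity_ranges["host"])
            _emit_hit(rows, t, int(rng.choice(_HOST_SPECIES)), pid, L, 1, rng)
            for _ in range(int(rng.integers(0, 3))):
                _emit_hit(rows, t, int(rng.choice(_HOST_SPECIES)),
                          pid - rng.uniform(2, 8), int(L * 0.8), 1, rng)
        elif src == FLAGELLATE:
            oname = truth.order[t]
            gname = truth.genus[t]
            L0 = int(rng.integers(400, 1500))
            if gname is not None:
                group = next(
                    g for g in _ORDER_SPECIES[oname]
                    if tax.name(tax.nodes[g[0]].parent) == gname)
                lo, hi = config.identity_ranges["genus"]
                pids = np.sort(rng.uniform(lo, hi, size=5))[::-1]
                for i, pid in enumerate(pids):
                    _emit_hit(rows, t, int(rng.choice(group)), pid,
                              L0 - 25 * i, 1, rng)
            elif oname is not None:
                genera = _ORDER_SPECIES[oname]
                lo, hi = config.identity_ranges["order"]
                pids = np.sort(rng.uniform(lo, hi, size=5))[::-1]
                for i, pid in enumerate(pids):
                    group = genera[i % len(genera)]
                    _emit_hit(rows, t, int(rng.choice(group)), pid,
                              L0 - 25 * i, 1, rng)
            else:
                # six hits alternating between two orders: no consensus
                o1, o2 = rng.choice(len(ORDERS), size=2, replace=False)
                lo, hi = config.identity_ranges["source"]
                pids = np.sort(rng.uniform(lo, hi, size=6))[::-1]
                for i, pid in enumerate(pids):
                    oname_i = ORDERS[(o1, o2)[i % 2]]
                    group = _ORDER_SPECIES[oname_i][0]
                    _emit_hit(rows, t, int(rng.choice(group)), pid,
                              L0 - 25 * i, 1, rng)
        else:
            flavor = truth.unclear_flavor[t]
            if flavor == "nohit":
                continue
            if flavor == "subthreshold":
                _emit_hit(rows, t, int(rng.choice(_HOST_SPECIES)),
                          rng.uniform(70, 85), 120, 1,
                          rng, evalue=10.0 ** (-float(rng.uniform(1, 4))))
            else:  # decoy: plausible best hit + conflicting off-clade hit
                focal = int(rng.choice(_HOST_SPECIES)) if rng.random() < 0.5 \
                    else int(rng.choice(
                        _ORDER_SPECIES[ORDERS[rng.integers(4)]][0]))
                _emit_hit(rows, t, focal,
                          rng.uniform(*config.identity_ranges["host"]),
                          500, 1, rng)
                # off-clade hit extending well beyond the best-hit region
                _emit_hit(rows, t, int(rng.choice(_DECOY_SPECIES)),
                          rng.uniform(80, 95), 400, 450, rng)
    from .source_classifier import HIT_COLUMNS
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# GO annotations and the fixture bundle


def simulate_annotations(truth: SyntheticTruth, config: SimConfig,
                         n_terms: int = 30) -> pd.DataFrame:
    """Random transcript -> GO term map with one planted enriched term.

    The planted term covers most worker-biased host transcripts and a
    small slice of the background, so the enrichment stage has signal to
    find.
    """
    rng = _rng(config, 4)
    terms = [f"GO:{7000000 + i}" for i in range(n_terms)]
    rows = []
    host = [t for t in truth.transcripts if truth.source[t] == TERMITE]
    for t in host:
        for term in rng.choice(terms, size=int(rng.poisson(1.5)),
                               replace=False):
            rows.append((t, term))
    planted = "GO:7999999"
    worker_biased = [t for t in host if truth.planted_lfc[t] < 0]
    for t in worker_biased:
        if rng.random() < 0.8:
            rows.append((t, planted))
    for t in host:
        if truth.planted_lfc[t] >= 0 and rng.random() < 0.05:
            rows.append((t, planted))
    return pd.DataFrame(sorted(set(rows)), columns=["transcript", "term"])


def write_fixture_bundle(config: SimConfig, outdir: str | Path
                         ) -> dict[str, Path]:
    """Generate and write the full bundle; returns the file paths.

    Files: taxonomy.tsv, hits.tsv (13 columns, no header), counts.tsv,
    castes.tsv, go.tsv, truth.json.  Identical configs (including seed)
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config)
    tax = generate_taxonomy(config)
    cm = simulate_counts(truth, config)
    hits = simulate_hits(truth, tax, config)
    annot = simulate_annotations(truth, config)

    paths = {name: outdir / f"{name}.tsv"
             for name in ("taxonomy", "hits", "counts", "castes", "go")}
    paths["truth"] = outdir / "truth.json"

    with open(paths["taxonomy"], "w") as fh:
        for taxid, parent, rank, name in _TAXA:
            fh.write(f"{taxid}\t{parent}\t{rank}\t{name}\n")
    hits.to_csv(paths["hits"], sep="\t", header=False, index=False)
    cm.to_tsv(paths["counts"], paths["castes"])
    annot.to_csv(paths["go"], sep="\t", header=False, index=False)
    with open(paths["truth"], "w") as fh:
        json.dump({
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
            "source": truth.source,
            "order": truth.order,
            "genus": truth.genus,
            "gene_class": truth.gene_class,
            "planted_lfc": truth.planted_lfc,
            "coupled_pairs": truth.coupled_pairs,
            "module_membership": truth.module_membership,
            "unclear_flavor": truth.unclear_flavor,
        }, fh, indent=1, sort_keys=True)
    return paths
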