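"""Synthetic stand-ins for the ocean gene-catalog inputs.

Generates everything the pipeline consumes, with known ground truth:

* a reference panel of diverged clades, each annotated with a metal-cofactor
  motif position and canonical class;
* query proteins mutated away from sampled references, with the motif
  overwritten to realise a drawn true class (lanthanide / calcium / unknown /
  incomplete);
* sample metadata with a phosphate gradient whose expected lanthanide
  fraction follows a logistic curve fLn = 1 / (1 + exp(-(b0 + b1 * PO4)));
* negative-binomial count tables scaled so the abundance-weighted lanthanide
  fraction of complete-domain genes has that expectation per sample.

All randomness flows from a single integer seed through per-stage
``numpy.random.default_rng([seed, stage])`` streams, so every artifact is
byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .panel import PanelEntry, ReferencePanel
from .records import AMINO_ACIDS, ProteinRecord, write_fasta

CLASSES = ("lanthanide", "calcium", "unknown", "incomplete")

# Field-standard family labels, cycled when more clades are requested.
CLADE_NAMES = (
    "XoxF5", "XoxF4", "ADH_type2b", "GDH_1a", "SDH",
    "ADH_type3", "ADH_type6a", "ADH_type2a", "GDH_1b", "ADH_type4",
)

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_CA_THIRD = np.frombuffer(b"ATS", dtype=np.uint8)
_D = ord("D")

# RNG stream ids per generator stage
_STREAM_PANEL, _STREAM_QUERIES, _STREAM_METADATA, _STREAM_COUNTS = 0, 1, 2, 3


def logistic(eta: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator; defaults mirror the observed field
    setting (motif-class split 61/12.5/26.5, negative fLn-phosphate slope)."""

    n_clades: int = 5
    refs_per_clade: int = 4
    ref_length: int = 400
    n_queries: int = 500
    divergence: float = 0.2
    indel_rate: float = 0.02
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "lanthanide": 0.61,
            "calcium": 0.125,
            "unknown": 0.265,
            "incomplete": 0.0,
        }
    )
    n_samples: int = 50
    phosphate_range: tuple[float, float] = (0.05, 2.5)  # umol/kg
    logit_intercept: float = 2.0   # b0
    logit_slope: float = -2.0      # b1, per (umol/kg)
    nb_dispersion: float = 5.0     # NB size k; variance mu + mu^2/k
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    seed: int = 0
    within_clade_divergence: float = 0.08

    def __post_init__(self) -> None:
        for name in ("n_clades", "refs_per_clade", "ref_length", "n_queries",
                     "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        mix = dict(self.class_mix)
        unknown_keys = set(mix) - set(CLASSES)
        if unknown_keys:
            raise ValueError(f"class_mix has unknown classes {sorted(unknown_keys)}")
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class_mix sums to {total}, expected 1 +/- 1e-12")
        if any(v < 0 for v in mix.values()):
            raise ValueError("class_mix proportions must be nonnegative")
        if not (0.0 <= self.divergence <= 1.0 and 0.0 <= self.indel_rate <= 1.0):
            raise ValueError("divergence and indel_rate must lie in [0, 1]")
        if self.divergence + self.indel_rate >= 1.0:
            raise ValueError("divergence + indel_rate must be < 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.phosphate_range
        if hi < lo:
            raise ValueError("phosphate_range must be (lo, hi) with hi >= lo")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")

    @property
    def mix_vector(self) -> np.ndarray:
        return np.array([dict(self.class_mix).get(c, 0.0) for c in CLASSES])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("phosphate_range", "library_size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "class_mix" in raw:
            raw["class_mix"] = dict(raw["class_mix"])
        return cls(**raw)


@dataclass
class TruthTable:
    """Ground truth for generated queries.

    ``genes`` is indexed by query id with columns true_class, true_clade,
    source_ref and length_aa; ``expected_abundance`` (filled in by
    :func:`make_abundance_counts`) holds the expected RPKM-scale abundance
    per (query, sample).
    """

    genes: pd.DataFrame
    expected_abundance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.genes.index.is_unique:
            raise ValueError("duplicate query ids in truth table")


def _mutate_substitutions(codes: np.ndarray, rate: float, rng: np.random.Generator,
                          protect: np.ndarray | None = None) -> np.ndarray:
    """Substitute residues at ``rate`` with a uniform kernel over the other 19."""
    out = codes.copy()
    if rate <= 0:
        return out
    hit = rng.random(out.size) < rate
    if protect is not None:
        hit &= ~protect
    idx = np.flatnonzero(hit)
    if idx.size:
        # draw an offset 1..19 from the current residue's alphabet index
        cur = np.searchsorted(_AA, out[idx])
        offs = rng.integers(1, 20, size=idx.size)
        out[idx] = _AA[(cur + offs) % 20]
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


def make_reference_panel(cfg: SyntheticConfig) -> ReferencePanel:
    """Build a panel of ``n_clades`` x ``refs_per_clade`` annotated references.

    Each clade descends from its own random ancestor (so between-clade
    identity sits at the ~5% random floor while within-clade identity stays
    high), and every reference carries its clade's canonical motif.
    """
    if cfg.ref_length < 50:
        raise ValueError("ref_length < 50: motif cannot be embedded with flanks")
    rng = np.random.default_rng([cfg.seed, _STREAM_PANEL])
    entries: list[PanelEntry] = []
    for ci in range(cfg.n_clades):
        clade = CLADE_NAMES[ci] if ci < len(CLADE_NAMES) else f"clade{ci:02d}"
        canonical = "calcium" if ci % 3 == 2 else "lanthanide"
        ancestor = _AA[rng.integers(0, 20, size=cfg.ref_length)]
        lo = max(25, int(0.2 * cfg.ref_length))
        hi = max(lo + 1, int(0.7 * cfg.ref_length))
        motif_start0 = int(rng.integers(lo, hi))  # 0-based
        for ri in range(cfg.refs_per_clade):
            codes = _mutate_substitutions(ancestor, cfg.within_clade_divergence, rng)
            codes[motif_start0] = _D
            codes[motif_start0 + 1] = _AA[rng.integers(0, 20)]
            if canonical == "lanthanide":
                codes[motif_start0 + 2] = _D
            else:
                codes[motif_start0 + 2] = _CA_THIRD[rng.integers(0, 3)]
            entries.append(
                PanelEntry(
                    id=f"REF_{clade}_{ri:03d}",
                    sequence=_codes_to_str(codes),
                    clade=clade,
                    motif_start=motif_start0 + 1,
                    canonical_class=canonical,
                    confirmed=(ri == 0),
                )
            )
    return ReferencePanel(entries)


def _realize_query(src: PanelEntry, true_class: str, cfg: SyntheticConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Mutate a copy of ``src`` and overwrite the motif to realise the class."""
    codes = np.frombuffer(src.sequence.encode(), dtype=np.uint8).copy()
    p0 = src.motif_start - 1
    motif_mask = np.zeros(codes.size, dtype=bool)
    motif_mask[p0 : p0 + 3] = True

    truncate = False
    if true_class == "incomplete":
        truncate = rng.random() < 0.5
        if truncate:
            cut = int(rng.integers(max(10, p0 // 2), p0))
            codes = codes[:cut]
            motif_mask = np.zeros(codes.size, dtype=bool)

    codes = _mutate_substitutions(codes, cfg.divergence, rng, protect=motif_mask)

    if true_class == "lanthanide":
        codes[p0], codes[p0 + 1], codes[p0 + 2] = _D, _AA[rng.integers(0, 20)], _D
    elif true_class == "calcium":
        codes[p0] = _D
        codes[p0 + 1] = _AA[rng.integers(0, 20)]
        codes[p0 + 2] = _CA_THIRD[rng.integers(0, 3)]
    elif true_class == "unknown":
        non_d = _AA[_AA != _D]
        third_pool = np.array(
            [a for a in _AA if a not in (set(_CA_THIRD.tolist()) | {_D})],
            dtype=np.uint8,
        )
        codes[p0] = non_d[rng.integers(0, non_d.size)]
        codes[p0 + 1] = _AA[rng.integers(0, 20)]
        codes[p0 + 2] = third_pool[rng.integers(0, third_pool.size)]
    elif not truncate:  # incomplete via motif-site deletion
        codes = np.delete(codes, slice(p0, p0 + 3))
        motif_mask = np.zeros(codes.size, dtype=bool)

    if cfg.indel_rate > 0:
        out: list[int] = []
        draws = rng.random(codes.size)
        for i, ch in enumerate(codes):
            if motif_mask[i]:
                out.append(ch)
                continue
            r = draws[i]
            if r < cfg.indel_rate / 2:
                continue  # deletion
            out.append(ch)
            if r < cfg.indel_rate:
                out.append(int(_AA[rng.integers(0, 20)]))  # insertion
        codes = np.array(out, dtype=np.uint8)
    return codes


def make_query_set(panel: ReferencePanel, cfg: SyntheticConfig
                   ) -> tuple[list[ProteinRecord], TruthTable]:
    """Draw ``n_queries`` mutated copies of panel references with known truth."""
    if len(panel) == 0:
        raise ValueError("panel is empty")
    rng = np.random.default_rng([cfg.seed, _STREAM_QUERIES])
    classes = rng.choice(len(CLASSES), size=cfg.n_queries, p=cfg.mix_vector)
    records: list[ProteinRecord] = []
    rows: list[dict] = []
    for qi in range(cfg.n_queries):
        true_class = CLASSES[classes[qi]]
        # 'incomplete' by truncation needs room before the motif; resample the
        # source reference if the motif sits too close to the N-terminus.
        for _attempt in range(100):
            src = panel.entries[rng.integers(0, len(panel))]
            if true_class != "incomplete" or src.motif_start - 1 >= 25:
                break
        else:
            raise RuntimeError("no reference long enough to truncate meaningfully")
        codes = _realize_query(src, true_class, cfg, rng)
        qid = f"Q{qi:06d}"
        records.append(ProteinRecord(id=qid, sequence=_codes_to_str(codes)))
        rows.append(
            {
                "query_id": qid,
                "true_class": true_class,
                "true_clade": src.clade,
                "source_ref": src.id,
                "length_aa": codes.size,
            }
        )
    genes = pd.DataFrame(rows).set_index("query_id")
    clades = set(panel.clades)
    assert set(genes["true_clade"]) <= clades
    return records, TruthTable(genes=genes)


def make_sample_metadata(cfg: SyntheticConfig) -> pd.DataFrame:
    """Sample metadata: phosphate gradient, temperature, depth layer, and the
    expected lanthanide fraction implied by the logistic model."""
    if cfg.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng([cfg.seed, _STREAM_METADATA])
    lo, hi = cfg.phosphate_range
    degenerate = math.isclose(lo, hi)
    phosphate = rng.uniform(lo, hi, size=cfg.n_samples) if not degenerate \
        else np.full(cfg.n_samples, lo)
    expected_fln = logistic(cfg.logit_intercept + cfg.logit_slope * phosphate)
    # colder where phosphate is high (HNLC-like), plus noise
    span = max(hi - lo, 1e-12)
    temperature = 27.0 - 9.0 * (phosphate - lo) / span + rng.normal(0.0, 1.5,
                                                                    cfg.n_samples)
    layers = np.array(["SO", "DCM", "MES"])[np.arange(cfg.n_samples) % 3]
    meta = pd.DataFrame(
        {
            "phosphate": phosphate,
            "temperature": temperature,
            "depth_layer": layers,
            "expected_fln": expected_fln,
        },
        index=pd.Index([f"S{si:04d}" for si in range(cfg.n_samples)], name="sample_id"),
    )
    meta.attrs["degenerate_phosphate_range"] = degenerate
    return meta


#: total expected RPKM (arbitrary units) shared by complete-domain genes per
#: sample; incomplete fragments get a fixed minor share on top.
_TOTAL_COMPLETE_RPKM = 100.0
_TOTAL_INCOMPLETE_RPKM = 10.0


@dataclass
class SimCounts:
    counts: pd.DataFrame          # genes x samples, integers
    gene_lengths: pd.Series       # bp (3 x residues)
    library_sizes: pd.Series      # mapped reads per sample


def expected_rpkm_matrix(truth: TruthTable, metadata: pd.DataFrame,
                         base_weights: np.ndarray) -> pd.DataFrame:
    """Expected RPKM per (gene, sample), scaled so the abundance-weighted
    lanthanide fraction over complete-domain genes equals expected_fln."""
    genes = truth.genes
    is_ln = (genes["true_class"] == "lanthanide").to_numpy()
    is_complete = (genes["true_class"] != "incomplete").to_numpy()
    is_other = is_complete & ~is_ln
    w = np.asarray(base_weights, dtype=float)

    ln_total = w[is_ln].sum()
    other_total = w[is_other].sum()
    inc_total = w[~is_complete].sum()

    exp = np.zeros((len(genes), len(metadata)))
    for si, fln in enumerate(metadata["expected_fln"].to_numpy()):
        col = np.zeros(len(genes))
        if ln_total > 0 and other_total > 0:
            col[is_ln] = fln * _TOTAL_COMPLETE_RPKM * w[is_ln] / ln_total
            col[is_other] = (1 - fln) * _TOTAL_COMPLETE_RPKM * w[is_other] / other_total
        elif ln_total > 0:
            col[is_ln] = _TOTAL_COMPLETE_RPKM * w[is_ln] / ln_total
        elif other_total > 0:
            col[is_other] = _TOTAL_COMPLETE_RPKM * w[is_other] / other_total
        if inc_total > 0:
            col[~is_complete] = _TOTAL_INCOMPLETE_RPKM * w[~is_complete] / inc_total
        exp[:, si] = col
    return pd.DataFrame(exp, index=genes.index, columns=metadata.index)


def make_abundance_counts(truth: TruthTable, metadata: pd.DataFrame,
                          cfg: SyntheticConfig) -> SimCounts:
    """Negative-binomial counts around the expected RPKM surface.

    Gene length in bp is 3 x protein residues (the catalog is nucleotide).
    Counts have mean mu = RPKM_expected * L_bp * N / 1e9 and variance
    mu + mu^2 / nb_dispersion.
    """
    if len(truth.genes) == 0 or len(metadata) == 0:
        raise ValueError("truth and metadata must be nonempty")
    rng = np.random.default_rng([cfg.seed, _STREAM_COUNTS])
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(truth.genes))
    exp_rpkm = expected_rpkm_matrix(truth, metadata, base)
    truth.expected_abundance = exp_rpkm

    lengths_bp = (3 * truth.genes["length_aa"]).rename("length_bp")
    lo, hi = cfg.library_size_range
    lib = pd.Series(
        rng.integers(lo, hi + 1, size=len(metadata)),
        index=metadata.index,
        name="library_size",
    )
    mu = exp_rpkm.to_numpy() * lengths_bp.to_numpy()[:, None] * lib.to_numpy()[None, :] / 1e9
    if np.isinf(cfg.nb_dispersion):
        counts = rng.poisson(mu)
    else:
        k = cfg.nb_dispersion
        p = k / (k + mu)
        counts = rng.negative_binomial(k, p)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=exp_rpkm.index,
                             columns=exp_rpkm.columns)
    return SimCounts(counts=counts_df, gene_lengths=lengths_bp, library_sizes=lib)


@dataclass
class Simulation:
    config: SyntheticConfig
    panel: ReferencePanel
    queries: list[ProteinRecord]
    truth: TruthTable
    metadata: pd.DataFrame
    tables: SimCounts


def simulate(cfg: SyntheticConfig) -> Simulation:
    """Run all generator stages in order under one seed."""
    panel = make_reference_panel(cfg)
    queries, truth = make_query_set(panel, cfg)
    metadata = make_sample_metadata(cfg)
    tables = make_abundance_counts(truth, metadata, cfg)
    return Simulation(cfg, panel, queries, truth, metadata, tables)


def write_simulation(sim: Simulation, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact as plain text (FASTA / TSV, '.' decimal)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "queries": outdir / "queries.faa",
        "panel_fasta": outdir / "panel.faa",
        "panel_tsv": outdir / "panel.tsv",
        "truth": outdir / "truth.tsv",
        "counts": outdir / "counts.tsv",
        "gene_lengths": outdir / "gene_lengths.tsv",
        "library_sizes": outdir / "library_sizes.tsv",
        "metadata": outdir / "metadata.tsv",
    }
    write_fasta(sim.queries, paths["queries"])
    sim.panel.write(paths["panel_fasta"], paths["panel_tsv"])
    sim.truth.genes.to_csv(paths["truth"], sep="\t")
    sim.tables.counts.to_csv(paths["counts"], sep="\t")
    sim.tables.gene_lengths.to_frame().to_csv(paths["gene_lengths"], sep="\t")
    sim.tables.library_sizes.to_frame().to_csv(paths["library_sizes"], sep="\t")
    sim.metadata.to_csv(paths["metadata"], sep="\t")
    return paths
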