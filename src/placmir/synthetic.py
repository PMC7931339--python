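"""Seeded generators for every input the pipeline consumes.

Three generators emulate the study design end-to-end, each returning its
outputs together with a :class:`SimulationTruth` manifest so downstream
stages can be tested against known ground truth:

* ``simulate_cq_array`` — a two-plate, one-pool-per-group qPCR array
  (667 assays by default) with intensity-dependent bias in the intervention
  pool, Gaussian Cq noise, and logistic high-Cq dropout.
* ``simulate_transcripts`` — random-background transcripts with 5'UTR/CDS/
  3'UTR layout and planted seed sites at recorded coordinates.
* ``simulate_cohort`` — a mother-offspring cohort (41 pairs by default,
  cells 11/9/10/11) with log-normal amino acids, per-cell expression shifts
  on dCq scale, linear outcome-predictor effects, and breastfeeding status.

Every generator is a pure function of its parameters and the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .qpcr_screen import CqMatrix, PLATES
from .seed_match import MatureMiRNA, TranscriptRegions, extract_seed, revcomp

__all__ = [
    "SimulationTruth",
    "simulate_cq_array",
    "simulate_transcripts",
    "simulate_cohort",
    "write_transcripts",
    "DEFAULT_CELL_COUNTS",
]


@dataclass
class SimulationTruth:
    """Ground-truth manifest for one simulated dataset (JSON-serializable)."""

    seed: int
    planted_de: dict[str, float] = field(default_factory=dict)
    bias_fn: list[float] = field(default_factory=list)
    planted_sites: dict[str, list[list]] = field(default_factory=dict)
    cohort_betas: dict[str, float] = field(default_factory=dict)
    cell_effects: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# qPCR array


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cq_array(
    n_assays: int = 667,
    base_cq_range: tuple[float, float] = (14.0, 36.0),
    de_spec: dict | None = None,
    bias_coeffs: tuple[float, ...] = (0.0,),
    noise_sd: float = 0.25,
    dropout_midpoint: float = 38.0,
    dropout_scale: float = 0.5,
    seed: int = 0,
) -> tuple[CqMatrix, SimulationTruth]:
    """Two-plate pooled array with planted effects, bias and dropout.

    Per assay: base Cq ~ uniform(base_cq_range); Con Cq = base + noise;
    N3 Cq = base - planted dCq + bias(base) + noise, where bias is a
    polynomial in the abundance axis (coefficients low-order first, argument
    centered mid-range).  Wells become undetermined with logistic
    probability in their Cq around ``dropout_midpoint``.  Plates alternate.

    ``de_spec`` is either a mapping assay_id -> dCq effect (positive = up in
    N3) or ``{"n": k, "delta": d}`` with optional ``"cq_window": (lo, hi)``
    to auto-place k effects on assays whose base Cq falls in the window.
    """
    if n_assays < 20:
        raise ValueError("n_assays must be >= 20")
    rng = np.random.default_rng(seed)
    ids = [f"sim-miR-{i + 1:04d}" for i in range(n_assays)]
    plates = np.array([PLATES[i % 2] for i in range(n_assays)])
    base = rng.uniform(*base_cq_range, size=n_assays)

    effects = np.zeros(n_assays)
    planted: dict[str, float] = {}
    if de_spec:
        if "n" in de_spec:
            k = int(de_spec["n"])
            delta = float(de_spec["delta"])
            lo, hi = de_spec.get("cq_window", base_cq_range)
            candidates = np.flatnonzero((base >= lo) & (base <= hi))
            if len(candidates) < k:
                raise ValueError(
                    f"only {len(candidates)} assays in Cq window for {k} effects"
                )
            chosen = rng.choice(candidates, size=k, replace=False)
            for i in chosen:
                effects[i] = delta
                planted[ids[i]] = delta
        else:
            index = {a: i for i, a in enumerate(ids)}
            for assay, delta in de_spec.items():
                if assay not in index:
                    raise ValueError(f"unknown assay in de_spec: {assay!r}")
                effects[index[assay]] = float(delta)
                planted[assay] = float(delta)

    mid = 0.5 * (base_cq_range[0] + base_cq_range[1])
    bias = sum(c * (base - mid) ** k for k, c in enumerate(bias_coeffs))
    cq_con = base + rng.normal(0.0, noise_sd, n_assays)
    cq_n3 = base - effects + bias + rng.normal(0.0, noise_sd, n_assays)

    rows = []
    for g, cqs in (("Con", cq_con), ("N3", cq_n3)):
        p_drop = _logistic((cqs - dropout_midpoint) / dropout_scale)
        undet = rng.random(n_assays) < p_drop
        rows.append(
            pd.DataFrame(
                {
                    "assay_id": ids,
                    "plate": plates,
                    "group": g,
                    "cq": np.where(undet, np.nan, cqs),
                    "undetermined": undet,
                }
            )
        )
    truth = SimulationTruth(seed=seed, planted_de=planted, bias_fn=list(bias_coeffs))
    return CqMatrix(pd.concat(rows, ignore_index=True)), truth


# ---------------------------------------------------------------------------
# transcripts with planted seed sites


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def simulate_transcripts(
    mirnas: list[MatureMiRNA],
    n_genes: int = 10,
    length_range: tuple[int, int] = (300, 1000),
    region_layout: tuple[float, float, float] = (0.15, 0.55, 0.30),
    plant_spec: list[dict] | None = None,
    seed: int = 0,
    max_attempts: int = 100,
) -> tuple[list[TranscriptRegions], SimulationTruth]:
    """Random transcripts with planted seed sites at recorded coordinates.

    ``plant_spec`` entries: {"gene": index-or-id, "mirna": id,
    "mismatches": 0|1|2, "region": optional label}.  Each plant inserts the
    reverse complement of the microRNA seed with the requested number of
    substitutions at a uniformly drawn position inside the region (whole
    transcript if no region given), redrawing on overlap with an earlier
    plant or a region boundary, and re-verifying the realized site after
    generation.
    """
    if length_range[0] < 60:
        raise ValueError("transcripts must be at least 60 nt")
    if abs(sum(region_layout) - 1.0) > 1e-9:
        raise ValueError("region_layout fractions must sum to 1")
    rng = np.random.default_rng(seed)
    mir_by_id = {m.id: m for m in mirnas}

    genes: list[TranscriptRegions] = []
    seqs: list[list[str]] = []
    for i in range(n_genes):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        n5 = max(1, int(round(region_layout[0] * length)))
        ncds = max(1, int(round(region_layout[1] * length)))
        regions = (
            ("5UTR", 1, n5),
            ("CDS", n5 + 1, n5 + ncds),
            ("3UTR", n5 + ncds + 1, length),
        )
        seq = _random_rna(rng, length)
        genes.append(TranscriptRegions(f"gene{i + 1:03d}", seq, regions))
        seqs.append(list(seq))

    truth = SimulationTruth(seed=seed)
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_genes)}
    for spec in plant_spec or []:
        gi = spec["gene"]
        if isinstance(gi, str):
            gi = next(i for i, g in enumerate(genes) if g.gene_id == gi)
        mirna = mir_by_id[spec["mirna"]]
        mm = int(spec.get("mismatches", 0))
        site_seq = list(revcomp(extract_seed(mirna)))
        if mm:
            pos_sub = rng.choice(7, size=mm, replace=False)
            for j in pos_sub:
                site_seq[j] = rng.choice([b for b in "ACGU" if b != site_seq[j]])
        tr = genes[gi]
        span = tr.region_span(spec["region"]) if "region" in spec else (1, len(tr.sequence))
        lo, hi = span[0], span[1] - 6
        if hi < lo:
            raise ValueError(f"region too short to plant a site in {tr.gene_id}")
        for attempt in range(max_attempts):
            start = int(rng.integers(lo, hi + 1))
            if all(start > e or start + 6 < s for s, e in occupied[gi]):
                break
        else:
            raise RuntimeError(f"could not place plant in {tr.gene_id} after {max_attempts} tries")
        seqs[gi][start - 1 : start + 6] = site_seq
        occupied[gi].append((start, start + 6))
        truth.planted_sites.setdefault(
            f"{mirna.id}|{tr.gene_id}", []
        ).append([start, mm])

    out = []
    for i, g in enumerate(genes):
        out.append(TranscriptRegions(g.gene_id, "".join(seqs[i]), g.regions))

    # re-check: every planted window must realize exactly its mismatch count
    for key, plants in truth.planted_sites.items():
        mid, gid = key.split("|")
        tr = next(g for g in out if g.gene_id == gid)
        pattern = revcomp(extract_seed(mir_by_id[mid]))
        for start, mm in plants:
            window = tr.sequence[start - 1 : start + 6]
            realized = sum(a != b for a, b in zip(window, pattern))
            if realized != mm:
                raise RuntimeError(
                    f"planted site destroyed at {gid}:{start} "
                    f"({realized} mismatches, expected {mm})"
                )
    return out, truth


def write_transcripts(
    genes: list[TranscriptRegions], fasta: str | Path, regions_tsv: str | Path
) -> None:
    with open(fasta, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.sequence}\n")
    rows = [
        {"gene_id": g.gene_id, "label": lab, "start": s, "end": e}
        for g in genes
        for lab, s, e in g.regions
    ]
    pd.DataFrame(rows).to_csv(regions_tsv, sep="\t", index=False)


def write_mirnas(mirnas: list[MatureMiRNA], fasta: str | Path) -> None:
    with open(fasta, "w") as fh:
        for m in mirnas:
            fh.write(f">{m.id}\n{m.sequence}\n")


# ---------------------------------------------------------------------------
# cohort

DEFAULT_CELL_COUNTS = {"Con-F": 11, "Con-M": 9, "N3-F": 10, "N3-M": 11}

# medians (µmol/L for plasma, µmol/g protein for placenta) in the range
# reported for this kind of cohort; log-normal spread sigma on the ln scale
DEFAULT_AMINO_MEDIANS = {
    "p15_tau": 108.0,
    "p15_trp": 43.0,
    "p32_tau": 95.0,
    "p32_trp": 38.0,
    "pl_tau": 330.0,
    "pl_trp": 2.5,
    "uc_tau": 560.0,
    "uc_trp": 150.0,
}
DEFAULT_OUTCOMES = {
    # name: (intercept, noise SD)
    "birthweight_g": (3400.0, 420.0),
    "placental_weight_g": (440.0, 90.0),
    "bw_pw_ratio": (7.7, 1.1),
    "weight_length_ratio": (66.0, 6.0),
    "fat_mass_g": (380.0, 110.0),
    "lean_mass_g": (2900.0, 330.0),
    "weight_1y_g": (9500.0, 1000.0),
}
DEFAULT_TARGETS = ("miR-99a", "mTOR", "SLC7A5", "SLC6A6")
REFERENCE_GENES = ("RNU24", "RNU6b", "miR-26b")


def simulate_cohort(
    n_pairs: int = 41,
    cell_counts: dict[str, int] | None = None,
    cell_effects: dict[str, float] | None = None,
    cohort_betas: dict[str, float] | None = None,
    targets: tuple[str, ...] = DEFAULT_TARGETS,
    amino_acid_medians: dict[str, float] | None = None,
    amino_sigma: float = 0.25,
    dcq_noise_sd: float = 0.6,
    breastfeeding_p_fully: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Mother-offspring cohort plus per-sample validation Cq records.

    ``cell_effects`` maps "target|cell" (e.g. "miR-99a|N3-F") to a dCq shift
    (negative dCq = higher expression).  ``cohort_betas`` maps
    "outcome|predictor" to a true slope; the outcome is then generated as
    intercept + beta * predictor + noise.  Amino acids are log-normal around
    the supplied medians.  Cell counts default to 11/9/10/11.
    """
    cells = dict(cell_counts or DEFAULT_CELL_COUNTS)
    if n_pairs != sum(cells.values()):
        # rescale the default split to the requested size
        base = list(DEFAULT_CELL_COUNTS)
        counts = {c: max(3, int(round(DEFAULT_CELL_COUNTS[c] * n_pairs / 41))) for c in base}
        while sum(counts.values()) > n_pairs:
            counts[max(counts, key=counts.get)] -= 1
        while sum(counts.values()) < n_pairs:
            counts[min(counts, key=counts.get)] += 1
        cells = counts
    if min(cells.values()) < 3:
        raise ValueError("every group-sex cell needs at least 3 pairs")

    rng = np.random.default_rng(seed)
    medians = dict(DEFAULT_AMINO_MEDIANS, **(amino_acid_medians or {}))
    cell_effects = cell_effects or {}
    cohort_betas = cohort_betas or {}

    rows = []
    i = 0
    for cell, count in cells.items():
        g, s = cell.split("-")
        for _ in range(count):
            i += 1
            rows.append({"pair_id": f"pair{i:03d}", "group": g, "sex": s})
    cohort = pd.DataFrame(rows)
    n = len(cohort)
    cohort["cell"] = cohort["group"] + "-" + cohort["sex"]

    for col, med in medians.items():
        cohort[col] = np.exp(np.log(med) + rng.normal(0.0, amino_sigma, n))

    # expression dCq per target: baseline + cell shift + noise
    for t in targets:
        base_dcq = rng.normal(4.0, 0.3)
        shift = cohort["cell"].map(
            lambda c: cell_effects.get(f"{t}|{c}", 0.0)
        ).to_numpy(dtype=float)
        cohort[f"dcq_{t}"] = base_dcq + shift + rng.normal(0.0, dcq_noise_sd, n)

    for name, (intercept, sd) in DEFAULT_OUTCOMES.items():
        y = intercept + rng.normal(0.0, sd, n)
        for key, beta in cohort_betas.items():
            outcome, predictor = key.split("|")
            if outcome == name:
                y = y + beta * (cohort[predictor] - cohort[predictor].mean())
        cohort[name] = y

    cohort["breastfeeding"] = np.where(
        rng.random(n) < breastfeeding_p_fully, "fully", "partial/formula"
    )

    # validation qPCR records: per-sample loading shift hits target and refs alike
    load = rng.normal(0.0, 0.4, n)
    vrows = []
    for t in targets:
        ref_base = {r: rng.normal(20.0, 0.5) for r in REFERENCE_GENES}
        for j in range(n):
            rec = {
                "sample_id": cohort.at[j, "pair_id"],
                "group": cohort.at[j, "group"],
                "sex": cohort.at[j, "sex"],
                "target_id": t,
            }
            refs = {
                f"cq_ref_{r}": ref_base[r] + load[j] + rng.normal(0.0, 0.15)
                for r in REFERENCE_GENES
            }
            ref_mean = np.mean(list(refs.values()))
            rec["cq_target"] = float(ref_mean + cohort.at[j, f"dcq_{t}"])
            rec.update(refs)
            vrows.append(rec)
    validation = pd.DataFrame(vrows)

    truth = SimulationTruth(
        seed=seed,
        cohort_betas=dict(cohort_betas),
        cell_effects=dict(cell_effects),
    )
    return cohort, validation, truth
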