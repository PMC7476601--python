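"""Synthetic glycoproteomics exports from a planted ground truth.

This module fabricates matched identification and precursor-area export
files — the two inputs the pipeline consumes — from a fully specified
"planted" glycoproteome: proteins with glycosylation sites, per-condition
glycoform distributions and occupancies, replicate samples, and the various
nuisances real exports contain (redundant PSMs of the same precursor,
multiple charge states, decoy and contaminant entries, rows with no
integrated area, rows below the score cutoff).

Because every planted glycoform's total AUC is an exact function of its
true proportion, a correct pipeline run over noiseless fixtures must
recover the planted proportions and occupancies to floating-point
precision; with multiplicative log-normal noise the recovery degrades
gracefully.  The generator is fully deterministic under a fixed seed, and
the injected nuisance rows are drawn from an independent random stream so
changing their rates never perturbs the signal rows.

What the generator does *not* emulate: chromatography (areas are planted,
not integrated from peaks), spectra, search-engine score behaviour beyond a
configurable range, and shared peptides between proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from pyteomics import mass as pmass

from .glycan_model import GlycanComposition, ModifiedPeptide

__all__ = [
    "SiteTruth",
    "ProteinTruth",
    "TruthModel",
    "FixtureSet",
    "N_GLYCAN_LIBRARY",
    "O_GLYCAN_LIBRARY",
    "generate",
    "default_truth",
    "random_assignment_case",
]

_G = GlycanComposition

# Small default glycan libraries: common biantennary/high-mannose N-glycan
# compositions and mucin-type core-1/core-2 O-glycan compositions.
N_GLYCAN_LIBRARY: tuple[GlycanComposition, ...] = tuple(
    _G.parse(s)
    for s in (
        "HexNAc(2)Hex(5)",
        "HexNAc(2)Hex(6)",
        "HexNAc(2)Hex(7)",
        "HexNAc(2)Hex(8)",
        "HexNAc(2)Hex(9)",
        "HexNAc(4)Hex(3)",
        "HexNAc(4)Hex(3)Fuc(1)",
        "HexNAc(4)Hex(4)Fuc(1)",
        "HexNAc(4)Hex(5)Fuc(1)",
        "HexNAc(4)Hex(5)NeuAc(1)",
        "HexNAc(4)Hex(5)NeuAc(2)",
        "HexNAc(4)Hex(5)Fuc(1)NeuAc(2)",
        "HexNAc(5)Hex(6)NeuAc(3)",
        "HexNAc(5)Hex(6)Fuc(1)NeuAc(3)",
        "HexNAc(6)Hex(7)NeuAc(4)",
    )
)
O_GLYCAN_LIBRARY: tuple[GlycanComposition, ...] = tuple(
    _G.parse(s)
    for s in (
        "HexNAc(1)",
        "HexNAc(1)Hex(1)",
        "HexNAc(1)Hex(1)NeuAc(1)",
        "HexNAc(1)Hex(1)NeuAc(2)",
        "HexNAc(1)NeuAc(1)",
        "HexNAc(2)Hex(1)",
        "HexNAc(2)Hex(2)",
        "HexNAc(2)Hex(2)NeuAc(2)",
    )
)

# residues allowed inside generated tryptic peptides (no C to avoid fixed
# carbamidomethylation, no K/R to keep cleavage sites terminal, no N/S/T so
# sequons appear only where planted)
_BODY_RESIDUES = "ADEFGHILMPQVWY"
_NONGLYCAN_DELTAS = (15.9949, 0.9840, 57.0215, -17.0265)

IDENT_HEADER = (
    "Protein Name",
    "Scan number",
    "Peptide",
    "Glycans NHFAGNa",
    "Modification Type(s)",
    "Score",
    "Calc. m/z",
    "Starting position",
)
AREA_HEADER = ("First Scan", "Area")


@dataclass
class SiteTruth:
    """One planted glycosylation site and its per-condition truth."""

    position: int  # 1-based protein coordinate of the glycosylated residue
    residue: str  # 'N' for N-linked, 'S'/'T' for O-linked
    peptide: str  # tryptic peptide sequence containing the site
    start: int  # protein coordinate of peptide[0]
    glycoforms: dict[str, dict[GlycanComposition, float]]  # condition -> dist
    occupancy: dict[str, float]  # condition -> occupied fraction
    base_auc: float = 1.0e7

    def __post_init__(self) -> None:
        offset = self.position - self.start
        if not 0 <= offset < len(self.peptide):
            raise ValueError(
                f"site {self.position} outside peptide starting at {self.start}"
            )
        if self.peptide[offset] != self.residue:
            raise ValueError(
                f"peptide residue at site {self.position} is "
                f"{self.peptide[offset]}, expected {self.residue}"
            )
        for cond, dist in self.glycoforms.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"glycoform proportions for condition {cond!r} sum to "
                    f"{total}, not 1"
                )
            if any(comp.is_empty for comp in dist):
                raise ValueError(
                    "the unglycosylated form is controlled by occupancy, not "
                    "by the glycoform distribution"
                )
        for cond, occ in self.occupancy.items():
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"occupancy {occ} outside [0, 1]")


@dataclass
class ProteinTruth:
    accession: str
    entry_name: str
    description: str
    sites: list[SiteTruth]

    @property
    def display_name(self) -> str:
        return f"sp|{self.accession}|{self.entry_name} {self.description}"


@dataclass
class TruthModel:
    """Complete specification of a planted glycoproteome experiment."""

    proteins: list[ProteinTruth]
    samples: list[tuple[str, str]]  # (sample label, condition)
    noise_sd: float = 0.25  # log-normal sigma on glycoform areas
    redundancy: int = 2  # PSM rows per precursor (>=1); extras are smaller
    decoy_rate: float = 0.1
    contaminant_rate: float = 0.05
    missing_area_rate: float = 0.05
    low_score_rate: float = 0.05
    score_range: tuple[float, float] = (250.0, 600.0)
    low_score_range: tuple[float, float] = (20.0, 180.0)
    charge_split: tuple[float, ...] = (0.7, 0.3)  # AUC fractions for z=2,3,...
    seed: int = 0

    def __post_init__(self) -> None:
        if self.redundancy < 1:
            raise ValueError("redundancy must be >= 1")
        labels = [label for label, _ in self.samples]
        if len(set(labels)) != len(labels):
            raise ValueError("sample labels must be unique")
        if abs(sum(self.charge_split) - 1.0) > 1e-9:
            raise ValueError("charge_split fractions must sum to 1")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for _, cond in self.samples:
            if cond not in seen:
                seen.append(cond)
        return seen


@dataclass
class FixtureSet:
    """Paths of everything one :func:`generate` call wrote."""

    outdir: Path
    ident_files: dict[str, Path]
    area_files: dict[str, Path]
    sample_map: Path
    truth_table: Path
    truth: "TruthModel" = None


def _peptide_row_string(site: SiteTruth, comp: GlycanComposition, flanks: tuple[str, str]) -> str:
    mods: tuple[tuple[int, float], ...] = ()
    if not comp.is_empty:
        pos = site.position - site.start + 1
        mods = ((pos, round(comp.mass, 4)),)
    pep = ModifiedPeptide(
        sequence=site.peptide,
        mods=mods,
        flank_n=flanks[0],
        flank_c=flanks[1],
        start=site.start,
    )
    return pep.render()


def _calc_mz(sequence: str, glycan_mass: float, charge: int) -> float:
    return pmass.fast_mass(sequence, charge=charge) + glycan_mass / charge


def _fmt_area(a: float) -> str:
    return repr(float(a))


def generate(truth: TruthModel, outdir: Union[str, Path]) -> FixtureSet:
    """Write per-sample ident/area export files plus sample map and truth table.

    For every sample, each planted glycoform's total AUC is
    ``base_auc x occupancy x proportion`` (times log-normal noise when
    ``noise_sd > 0``), split across charge states 2 and 3 so aggregation
    across calculated m/z values is exercised; each precursor is emitted
    ``redundancy`` times with strictly decreasing areas so unique-PSM
    selection is exercised.  Decoy, contaminant, missing-area, and
    sub-cutoff rows are injected from an independent random stream at the
    configured rates; every injected row is one a correct pipeline must
    discard, so planted proportions are invariant to the rates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base_ss = np.random.SeedSequence(truth.seed)
    streams = base_ss.spawn(2 * len(truth.samples))

    ident_files: dict[str, Path] = {}
    area_files: dict[str, Path] = {}
    truth_rows: list[dict] = []
    map_rows: list[str] = ["ident,area,sample,group"]

    for i, (label, condition) in enumerate(truth.samples):
        rng = np.random.default_rng(streams[2 * i])
        rng_inject = np.random.default_rng(streams[2 * i + 1])
        ident_lines: list[str] = [",".join(IDENT_HEADER)]
        area_lines: list[str] = [",".join(AREA_HEADER)]
        scan = 1000
        inject_scan = 1_000_000

        def emit(protein_name: str, site: SiteTruth, comp: GlycanComposition,
                 score: float, this_scan: int, charge: int, start: int) -> str:
            glycan_text = str(comp)
            mod_types = "Glycan" if not comp.is_empty else ""
            pep_str = _peptide_row_string(site, comp, ("K", "A"))
            mz = _calc_mz(site.peptide, comp.mass, charge)
            return ",".join(
                [
                    f'"{protein_name}"',
                    f"{label}.{this_scan}.{this_scan}.{charge}",
                    pep_str,
                    glycan_text,
                    mod_types,
                    f"{score:.1f}",
                    f"{mz:.4f}",
                    str(start),
                ]
            )

        for protein in truth.proteins:
            for site in protein.sites:
                dist = site.glycoforms[condition]
                occ = site.occupancy[condition]
                forms: list[tuple[GlycanComposition, float]] = [
                    (comp, occ * p) for comp, p in dist.items()
                ]
                if occ < 1.0:
                    forms.append((GlycanComposition.empty(), 1.0 - occ))
                for comp, weight in forms:
                    noise = rng.lognormal(0.0, truth.noise_sd)
                    form_total = site.base_auc * weight * noise
                    for charge, frac in zip((2, 3), truth.charge_split):
                        area = form_total * frac
                        for dup in range(truth.redundancy):
                            scan += 1
                            score = rng.uniform(*truth.score_range)
                            dup_area = area * (0.5 ** dup)
                            ident_lines.append(
                                emit(
                                    protein.display_name,
                                    site,
                                    comp,
                                    score,
                                    scan,
                                    charge,
                                    site.start,
                                )
                            )
                            area_lines.append(f"{scan},{_fmt_area(dup_area)}")
                    # nuisance rows tied to this glycoform, from the
                    # independent stream and a disjoint scan range
                    if rng_inject.random() < truth.decoy_rate:
                        inject_scan += 1
                        ident_lines.append(
                            emit(
                                f">Reverse {protein.display_name}",
                                site,
                                comp,
                                rng_inject.uniform(*truth.score_range),
                                inject_scan,
                                2,
                                site.start,
                            )
                        )
                        area_lines.append(
                            f"{inject_scan},{_fmt_area(form_total)}"
                        )
                    if rng_inject.random() < truth.contaminant_rate:
                        inject_scan += 1
                        ident_lines.append(
                            emit(
                                "Common contaminant protein Trypsin",
                                site,
                                comp,
                                rng_inject.uniform(*truth.score_range),
                                inject_scan,
                                2,
                                site.start,
                            )
                        )
                        area_lines.append(
                            f"{inject_scan},{_fmt_area(form_total)}"
                        )
                    if rng_inject.random() < truth.missing_area_rate:
                        inject_scan += 1
                        ident_lines.append(
                            emit(
                                protein.display_name,
                                site,
                                comp,
                                rng_inject.uniform(*truth.score_range),
                                inject_scan,
                                2,
                                site.start,
                            )
                        )
                        # no matching area row on purpose
                    if rng_inject.random() < truth.low_score_rate:
                        inject_scan += 1
                        ident_lines.append(
                            emit(
                                protein.display_name,
                                site,
                                comp,
                                rng_inject.uniform(*truth.low_score_range),
                                inject_scan,
                                2,
                                site.start,
                            )
                        )
                        area_lines.append(
                            f"{inject_scan},{_fmt_area(2.0 * site.base_auc)}"
                        )
                # planted truth for this sample
                for comp, p in dist.items():
                    truth_rows.append(
                        {
                            "sample": label,
                            "condition": condition,
                            "accession": protein.accession,
                            "site_position": site.position,
                            "residue": site.residue,
                            "peptide": site.peptide,
                            "start": site.start,
                            "composition": str(comp),
                            "proportion_with_unglyc": occ * p,
                            "proportion_without_unglyc": p,
                            "occupancy": occ,
                        }
                    )
                if occ < 1.0:
                    truth_rows.append(
                        {
                            "sample": label,
                            "condition": condition,
                            "accession": protein.accession,
                            "site_position": site.position,
                            "residue": site.residue,
                            "peptide": site.peptide,
                            "start": site.start,
                            "composition": "Unglycosylated",
                            "proportion_with_unglyc": 1.0 - occ,
                            "proportion_without_unglyc": float("nan"),
                            "occupancy": occ,
                        }
                    )

        ident_path = outdir / f"{label}_ident.csv"
        area_path = outdir / f"{label}_area.csv"
        ident_path.write_text("\n".join(ident_lines) + "\n")
        area_path.write_text("\n".join(area_lines) + "\n")
        ident_files[label] = ident_path
        area_files[label] = area_path
        map_rows.append(f"{ident_path.name},{area_path.name},{label},{condition}")

    sample_map = outdir / "sample_map.csv"
    sample_map.write_text("\n".join(map_rows) + "\n")
    import pandas as pd

    truth_table = outdir / "truth_table.csv"
    pd.DataFrame(truth_rows).to_csv(truth_table, index=False)
    return FixtureSet(
        outdir=outdir,
        ident_files=ident_files,
        area_files=area_files,
        sample_map=sample_map,
        truth_table=truth_table,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# randomized truth construction
# ---------------------------------------------------------------------------

def _random_peptide_with_site(
    rng: np.random.Generator, residue: str, length: Optional[int] = None
) -> tuple[str, int]:
    """Random tryptic-looking peptide containing one glyco residue.

    Returns the sequence and the 1-based offset of the site within it.  For
    an N-linked site the N-X-S/T sequon is planted (X never proline here);
    the rest of the body avoids N/S/T so no accidental second site exists.
    """
    n = int(length or rng.integers(8, 16))
    body = [str(r) for r in rng.choice(list(_BODY_RESIDUES), size=n - 1)]
    body.append("K" if rng.random() < 0.5 else "R")
    if residue == "N":
        offset = int(rng.integers(1, n - 2))  # leave room for the sequon
        body[offset - 1] = "N"
        body[offset + 1] = "S" if rng.random() < 0.5 else "T"
    else:
        offset = int(rng.integers(1, n))
        body[offset - 1] = residue
    return "".join(body), offset


def default_truth(
    seed: int = 0,
    n_replicates: int = 3,
    conditions: tuple[str, str] = ("control", "disease"),
    noise_sd: float = 0.25,
    redundancy: int = 2,
    decoy_rate: float = 0.1,
    contaminant_rate: float = 0.05,
    missing_area_rate: float = 0.05,
    low_score_rate: float = 0.05,
) -> TruthModel:
    """A study-scale planted glycoproteome: 3 proteins, 6 sites.

    Two proteins carry two N-linked sites each and one carries two O-linked
    sites; every site gets 2-4 glycoforms drawn from the default libraries,
    per-condition Dirichlet proportions, and per-condition occupancy in
    [0.55, 0.95].  Two conditions with ``n_replicates`` samples each.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 915]))
    protein_specs = [
        ("P10923", "GLYA_HUMAN", "Synthetic glycoprotein alpha", "N", N_GLYCAN_LIBRARY),
        ("Q96712", "GLYB_HUMAN", "Synthetic glycoprotein beta", "N", N_GLYCAN_LIBRARY),
        ("O43523", "GLYC_HUMAN", "Synthetic mucin gamma", "S", O_GLYCAN_LIBRARY),
    ]
    proteins: list[ProteinTruth] = []
    used_peptides: set[str] = set()
    for accession, entry, desc, residue, library in protein_specs:
        sites: list[SiteTruth] = []
        for site_index in range(2):
            while True:
                peptide, offset = _random_peptide_with_site(rng, residue)
                if peptide not in used_peptides:
                    used_peptides.add(peptide)
                    break
            position = 100 + 150 * site_index + int(rng.integers(0, 30))
            start = position - offset + 1
            n_forms = int(rng.integers(2, 5))
            chosen = [library[j] for j in rng.choice(len(library), size=n_forms, replace=False)]
            glycoforms: dict[str, dict[GlycanComposition, float]] = {}
            occupancy: dict[str, float] = {}
            for cond in conditions:
                raw = rng.dirichlet(np.full(n_forms, 2.0))
                p = raw / raw.sum()
                glycoforms[cond] = {comp: float(x) for comp, x in zip(chosen, p)}
                occupancy[cond] = float(rng.uniform(0.55, 0.95))
            sites.append(
                SiteTruth(
                    position=position,
                    residue=residue,
                    peptide=peptide,
                    start=start,
                    glycoforms=glycoforms,
                    occupancy=occupancy,
                    base_auc=float(rng.uniform(5e6, 5e7)),
                )
            )
        proteins.append(ProteinTruth(accession, entry, desc, sites))
    samples = [
        (f"{cond}_{r + 1}", cond) for cond in conditions for r in range(n_replicates)
    ]
    return TruthModel(
        proteins=proteins,
        samples=samples,
        noise_sd=noise_sd,
        redundancy=redundancy,
        decoy_rate=decoy_rate,
        contaminant_rate=contaminant_rate,
        missing_area_rate=missing_area_rate,
        low_score_rate=low_score_rate,
        seed=seed,
    )


def random_assignment_case(
    rng: np.random.Generator,
    n_decoy_mods: Optional[int] = None,
) -> tuple[ModifiedPeptide, GlycanComposition, int]:
    """A random glycopeptide with one planted glycan and decoy mods.

    Returns the peptide (glycan delta mass printed to 4 decimals, like an
    export would), the planted composition, and the true 1-based site.
    Decoy mods (oxidation, deamidation, carbamidomethyl, pyro-Glu) land on
    other residues; their masses are far from any glycan mass, so the case
    is always unambiguous.
    """
    library = N_GLYCAN_LIBRARY + O_GLYCAN_LIBRARY
    comp = library[int(rng.integers(len(library)))]
    residue = "N" if comp in N_GLYCAN_LIBRARY else "S"
    sequence, site = _random_peptide_with_site(rng, residue)
    mods: list[tuple[int, float]] = [(site, round(comp.mass, 4))]
    n_decoys = int(rng.integers(0, 4)) if n_decoy_mods is None else n_decoy_mods
    free_positions = [p for p in range(1, len(sequence) + 1) if p != site]
    rng.shuffle(free_positions)
    for pos in free_positions[:n_decoys]:
        mods.append((pos, float(_NONGLYCAN_DELTAS[int(rng.integers(len(_NONGLYCAN_DELTAS)))])))
    rng.shuffle(mods)
    peptide = ModifiedPeptide(sequence=sequence, mods=tuple(mods), start=int(rng.integers(1, 500)))
    return peptide, comp, site


def load_truth(path: Union[str, Path]) -> TruthModel:
    """Load a TruthModel from a YAML/JSON config file.

    Compositions are given as strings, distributions as composition→
    proportion maps; see :func:`default_truth` for the schema by example.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    proteins = []
    for p in data["proteins"]:
        sites = []
        for s in p["sites"]:
            glycoforms = {
                cond: {_G.parse(c): float(x) for c, x in dist.items()}
                for cond, dist in s["glycoforms"].items()
            }
            sites.append(
                SiteTruth(
                    position=int(s["position"]),
                    residue=s["residue"],
                    peptide=s["peptide"],
                    start=int(s["start"]),
                    glycoforms=glycoforms,
                    occupancy={c: float(v) for c, v in s["occupancy"].items()},
                    base_auc=float(s.get("base_auc", 1.0e7)),
                )
            )
        proteins.append(
            ProteinTruth(
                accession=p["accession"],
                entry_name=p.get("entry_name", p["accession"]),
                description=p.get("description", ""),
                sites=sites,
            )
        )
    samples = [(s["label"], s["condition"]) for s in data["samples"]]
    kwargs = {
        k: data[k]
        for k in (
            "noise_sd",
            "redundancy",
            "decoy_rate",
            "contaminant_rate",
            "missing_area_rate",
            "low_score_rate",
            "seed",
        )
        if k in data
    }
    return TruthModel(proteins=proteins, samples=samples, **kwargs)
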