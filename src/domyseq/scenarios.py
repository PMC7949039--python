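"""Packaged synthetic scenarios mirroring the four published mapping screens.

Each scenario builds a ~9-kb synthetic circular prey plasmid carrying a
random, in-frame stop-free ORF, and a run configuration whose binding
truth is the interval reported for the corresponding real screen:

* ``craf_kras``   — CRAF prey vs KRAS bait; Ras-binding-domain truth aa 58-128
* ``craf_mek1``   — CRAF vs MEK1; truth aa 310-375 with a forbidden interval
                    abutting the 3' edge (fragments reaching into it never
                    bind, reproducing the sharp 3' coverage edge)
* ``rgl3_rit1``   — RGL3 vs RIT1; Ras-association-domain truth aa 614-695
* ``mdm2_p53``    — MDM2 vs p53; N-terminal pocket truth aa 28-107 plus a
                    seeded transactivating EVYQVTVYQ peptide at aa 274-282
* ``unselected_control`` — the pre-selection library (no reporter model)

Real nucleotide sequences are deliberately not bundled; the scenarios are
synthetic ORFs that carry the published interval coordinates as simulation
ground truth, so every test runs without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .library_sim import BindingModel, ShearModel
from .pipeline import CallerParams, RunConfig
from .reads import ErrorModel
from .reference import AaInterval, PlasmidMap, translate, write_plasmid

#: Shear fractions used in the source protocol (mean bp); SD set to 25% of
#: the mean, the broad spread characteristic of acoustic shearing (the
#: nominally 350-bp fraction carries real mass down to ~200 bp).
SHEAR_PRESETS = {200: 50, 350: 88, 500: 125, 700: 175, 1000: 250}

PLASMID_LENGTH = 9_000
CDS_START = 2_000

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_CODON_FOR = {  # one representative codon per residue, for seeded peptides
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

SELF_ACTIVATING_PEPTIDE = "EVYQVTVYQ"


@dataclass(frozen=True)
class Scenario:
    name: str
    orf_aa_length: int
    true_interval: AaInterval | None
    forbidden_interval: AaInterval | None = None
    tad_interval: AaInterval | None = None
    tad_penetrance: float = 1.0
    shear_preset: int = 350
    seeded_peptides: tuple[tuple[int, str], ...] = ()  # (start_res, peptide)
    # secondary-call floor as a fraction of max depth; the p53/MDM2-style
    # two-peak read-out needs a floor below the sub-plateau TAD peak
    secondary_floor: float = 0.5


SCENARIOS: dict[str, Scenario] = {
    "craf_kras": Scenario("craf_kras", 700, AaInterval(58, 128)),
    "craf_mek1": Scenario(
        "craf_mek1", 700, AaInterval(310, 375), forbidden_interval=AaInterval(378, 389)
    ),
    "rgl3_rit1": Scenario("rgl3_rit1", 750, AaInterval(614, 695)),
    "mdm2_p53": Scenario(
        "mdm2_p53",
        491,
        AaInterval(28, 107),
        tad_interval=AaInterval(274, 282),
        tad_penetrance=0.15,
        seeded_peptides=((274, SELF_ACTIVATING_PEPTIDE),),
        secondary_floor=0.4,
    ),
    "unselected_control": Scenario("unselected_control", 700, None),
}


def synthesize_plasmid(scenario: Scenario, seed: int) -> PlasmidMap:
    """Random ~9-kb vector with a stop-free random ORF at a fixed offset."""
    rng = np.random.default_rng(seed)
    naa = scenario.orf_aa_length
    codons = ["ATG"] + [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=naa - 1)
    ]
    for start_res, peptide in scenario.seeded_peptides:
        for j, aa in enumerate(peptide):
            codons[start_res - 1 + j] = _CODON_FOR[aa]
    orf = "".join(codons) + "TAA"
    backbone_len = PLASMID_LENGTH - len(orf)
    backbone = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=backbone_len)])
    seq = backbone[:CDS_START] + orf + backbone[CDS_START:]
    plasmid = PlasmidMap(
        name=f"pPREY_{scenario.name}",
        sequence=seq,
        cds_start=CDS_START,
        cds_aa_length=naa,
        vector_features=[
            ("ori", 200, 800),
            ("AD_fusion_tag", 1700, CDS_START),
            ("AmpR", 7300, 8200),
        ],
    )
    # stop-free by construction; verify on generation
    pep = plasmid.orf_peptide()
    assert "*" not in pep and len(pep) == naa
    return plasmid


def make_scenario(
    name: str,
    seed: int = 7,
    n_fragments: int = 50_000,
    out_dir: str | Path = "run",
    substitution_rate: float = 0.0,
) -> tuple[PlasmidMap, RunConfig]:
    """Build the scenario plasmid and its full run configuration."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    sc = SCENARIOS[name]
    plasmid = synthesize_plasmid(sc, seed)
    mean = float(sc.shear_preset)
    shear = ShearModel(
        mean_len=mean,
        sd_len=float(SHEAR_PRESETS[sc.shear_preset]),
        min_len=100,
        n_fragments=n_fragments,
        seed=seed,
    )
    binding = None
    if sc.true_interval is not None or sc.tad_interval is not None:
        binding = BindingModel(
            true_interval=sc.true_interval,
            forbidden_interval=sc.forbidden_interval,
            tad_intervals=(sc.tad_interval,) if sc.tad_interval else (),
            tad_penetrance=sc.tad_penetrance,
        )
    config = RunConfig(
        shear=shear,
        binding=binding,
        errors=ErrorModel(substitution_rate=substitution_rate),
        caller=CallerParams(secondary_floor=sc.secondary_floor),
        seed=seed,
        out_dir=str(out_dir),
    )
    return plasmid, config


def emit_scenario(name: str, seed: int, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write the scenario FASTA, plasmid sidecar and run config to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plasmid, config = make_scenario(name, seed=seed, out_dir=out)
    fasta = out / f"{plasmid.name}.fasta"
    sidecar = out / f"{plasmid.name}.plasmid.yaml"
    write_plasmid(plasmid, fasta, sidecar)
    config.reference_fasta = str(fasta)
    config.reference_config = str(sidecar)
    cfg_path = out / f"{name}.config.yaml"
    config.to_yaml(cfg_path)
    return fasta, sidecar, cfg_path
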