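"""End-to-end orchestration: simulate -> sequence -> map -> frames ->
coverage -> plateau call -> TAD audit, with deterministic seeding and
reproducible on-disk artifacts.

One master seed drives the whole run; each stochastic stage draws from its
own child stream spawned from the master, so stages can be re-run in
isolation and two runs with identical config and seed are byte-identical.
Every artifact carries a provenance header (seed, config hash, schema
version).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import caller as caller_mod
from . import coverage as cov
from . import library_sim as lib
from . import mapping as mp
from . import reads as rd
from . import tad as tad_mod
from .reference import AaInterval, PlasmidMap, read_plasmid

SCHEMA_VERSION = "1"

_STAGES = ("shear", "selection", "amplify", "reads")


class ConfigError(ValueError):
    """Unknown or invalid configuration keys (fail-fast)."""


@dataclass(frozen=True)
class CallerParams:
    tau: float = 0.99
    secondary_floor: float = 0.5
    min_secondary_run: int = 10


@dataclass
class RunConfig:
    """Validated configuration for a full run.

    ``binding=None`` means no reporter selection (the whole library is
    sequenced — a pre-selection control).  ``reference_fasta`` and
    ``reference_config`` point at the plasmid FASTA plus its annotation
    sidecar; they may stay empty when the plasmid object is supplied
    directly to :func:`run_pipeline`.
    """

    shear: lib.ShearModel = field(default_factory=lib.ShearModel)
    binding: lib.BindingModel | None = None
    errors: rd.ErrorModel = field(default_factory=rd.ErrorModel)
    mapper: mp.AlignmentParams | None = None
    caller: CallerParams = field(default_factory=CallerParams)
    read_len: int = 150
    growth_mean_copies: float = 1.0
    seed: int = 7
    out_dir: str = "run"
    reference_fasta: str = ""
    reference_config: str = ""

    def __post_init__(self) -> None:
        if self.mapper is None:
            # permissive insert bounds that still exclude chimeric arcs
            self.mapper = mp.AlignmentParams(
                max_insert=int(self.shear.mean_len + 6 * self.shear.sd_len)
            )

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def interval(iv):
            return None if iv is None else [iv.start_res, iv.end_res]

        d = {
            "schema_version": SCHEMA_VERSION,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "reference": {"fasta": self.reference_fasta, "config": self.reference_config},
            "shear": dataclasses.asdict(self.shear),
            "binding": None
            if self.binding is None
            else {
                "true_interval": interval(self.binding.true_interval),
                "coverage_stringency": self.binding.coverage_stringency,
                "forbidden_interval": interval(self.binding.forbidden_interval),
                "tad_intervals": [interval(t) for t in self.binding.tad_intervals],
                "tad_penetrance": self.binding.tad_penetrance,
                "background_rate": self.binding.background_rate,
            },
            "reads": {
                "read_len": self.read_len,
                "substitution_rate": self.errors.substitution_rate,
            },
            "mapper": dataclasses.asdict(self.mapper),
            "caller": dataclasses.asdict(self.caller),
            "growth_mean_copies": self.growth_mean_copies,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        version = str(d.pop("schema_version", SCHEMA_VERSION))
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported config schema version {version}")
        known = {
            "seed", "out_dir", "reference", "shear", "binding", "reads",
            "mapper", "caller", "growth_mean_copies",
        }
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

        def check(block: dict, allowed, name):
            extra = set(block) - set(allowed)
            if extra:
                raise ConfigError(f"unknown keys in [{name}]: {sorted(extra)}")
            return block

        def interval(v):
            return None if v is None else AaInterval(int(v[0]), int(v[1]))

        ref = check(d.get("reference") or {}, {"fasta", "config"}, "reference")
        shear = lib.ShearModel(
            **check(d.get("shear") or {}, {f.name for f in dataclasses.fields(lib.ShearModel)}, "shear")
        )
        binding = None
        if d.get("binding") is not None:
            b = check(
                d["binding"],
                {
                    "true_interval", "coverage_stringency", "forbidden_interval",
                    "tad_intervals", "tad_penetrance", "background_rate",
                },
                "binding",
            )
            binding = lib.BindingModel(
                true_interval=interval(b.get("true_interval")),
                coverage_stringency=float(b.get("coverage_stringency", 0.0)),
                forbidden_interval=interval(b.get("forbidden_interval")),
                tad_intervals=tuple(interval(t) for t in b.get("tad_intervals") or []),
                tad_penetrance=float(b.get("tad_penetrance", 1.0)),
                background_rate=float(b.get("background_rate", 0.0)),
            )
        reads_blk = check(d.get("reads") or {}, {"read_len", "substitution_rate"}, "reads")
        mapper = None
        if d.get("mapper"):
            mapper = mp.AlignmentParams(
                **check(d["mapper"], {f.name for f in dataclasses.fields(mp.AlignmentParams)}, "mapper")
            )
        caller = CallerParams(
            **check(d.get("caller") or {}, {f.name for f in dataclasses.fields(CallerParams)}, "caller")
        )
        return cls(
            shear=shear,
            binding=binding,
            errors=rd.ErrorModel(float(reads_blk.get("substitution_rate", 0.0))),
            mapper=mapper,
            caller=caller,
            read_len=int(reads_blk.get("read_len", 150)),
            growth_mean_copies=float(d.get("growth_mean_copies", 1.0)),
            seed=int(d.get("seed", 7)),
            out_dir=str(d.get("out_dir", "run")),
            reference_fasta=str(ref.get("fasta", "")),
            reference_config=str(ref.get("config", "")),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        # machine-local paths excluded so identical runs hash identically
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("reference", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Per-stage child RNG streams derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


@dataclass
class RunReport:
    """Per-stage record counts plus the analytic results of one run."""

    seed: int
    config_hash: str
    n_fragments: int = 0
    n_selected: int = 0
    n_pairs: int = 0
    n_mapped: int = 0
    n_proper: int = 0
    n_unique_pe: int = 0
    n_inframe: int = 0
    selection_by_cause: dict = field(default_factory=dict)
    frame_counts: dict = field(default_factory=dict)
    frame_mean_pct: float = float("nan")
    frame_sd_pct: float = float("nan")
    call: caller_mod.DomainCall | None = None
    tad_hits: list = field(default_factory=list)

    def validate_funnel(self) -> None:
        funnel = [self.n_pairs, self.n_mapped, self.n_proper, self.n_unique_pe, self.n_inframe]
        if any(a < b for a, b in zip(funnel, funnel[1:])):
            raise AssertionError(f"count funnel not monotone: {funnel}")

    def to_text(self) -> str:
        lines = [
            f"domyseq run report (seed={self.seed} config={self.config_hash})",
            f"fragments sheared   : {self.n_fragments}",
            f"fragments selected  : {self.n_selected} {self.selection_by_cause}",
            f"read pairs          : {self.n_pairs}",
            f"pairs mapped        : {self.n_mapped}",
            f"proper pairs        : {self.n_proper}",
            f"UniquePE fragments  : {self.n_unique_pe}",
            f"InFrame fragments   : {self.n_inframe}",
            f"frame counts        : {self.frame_counts}",
            f"frame mean/sd (%)   : {self.frame_mean_pct:.2f} +/- {self.frame_sd_pct:.2f}",
        ]
        if self.call is not None:
            lines.append(f"primary call        : {self.call.interval} depth={self.call.plateau_depth}")
            lines.append(
                f"flank slopes (aa)   : left={self.call.left_slope_aa}"
                f"{'*' if self.call.left_censored else ''} "
                f"right={self.call.right_slope_aa}{'*' if self.call.right_censored else ''}"
            )
            for s in self.call.secondary_calls:
                flag = " [possible_self_activation]" if s.possible_self_activation else ""
                lines.append(f"secondary call      : {s.interval} depth={s.plateau_depth}{flag}")
        else:
            lines.append("primary call        : no_call")
        lines.append(f"TAD hits (orf)      : {sum(1 for h in self.tad_hits if h.source == 'orf')}")
        return "\n".join(lines) + "\n"


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: RunConfig, plasmid: PlasmidMap | None = None) -> RunReport:
    """Execute the full simulated experiment and write all artifacts.

    Stages: shear -> selection -> (growth) -> reads -> map -> dedup ->
    frames -> coverage -> plateau call -> TAD audit -> report.
    """
    if plasmid is None:
        if not config.reference_fasta:
            raise ConfigError("no plasmid: set reference.fasta/config or pass one in")
        plasmid = read_plasmid(config.reference_fasta, config.reference_config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = stage_rngs(config.seed)
    header = [
        f"domyseq schema={SCHEMA_VERSION} seed={config.seed} "
        f"config_hash={config.config_hash()} plasmid={plasmid.config_hash()}"
    ]
    report = RunReport(seed=config.seed, config_hash=config.config_hash())
    config.to_yaml(out / "config.yaml")

    # -- simulate library + selection --------------------------------------
    fragments = lib.shear_plasmid(plasmid, config.shear, rngs["shear"])
    report.n_fragments = len(fragments)
    lib.write_fragments_tsv(fragments, plasmid, out / "fragments.tsv", header)
    if config.binding is not None:
        selected, summary = lib.simulate_selection(
            fragments, plasmid, config.binding, rng=rngs["selection"]
        )
        report.selection_by_cause = summary.by_cause
    else:
        selected = fragments
        report.selection_by_cause = {"unselected": len(fragments)}
    report.n_selected = len(selected)
    selected = lib.amplify(selected, config.growth_mean_copies, rngs["amplify"])
    lib.write_fragments_tsv(selected, plasmid, out / "selected.tsv", header)

    # -- sequencing ---------------------------------------------------------
    pairs = rd.simulate_reads(
        selected, plasmid, config.read_len, config.errors, rng=rngs["reads"]
    )
    rd.write_fastq(pairs, out / "reads_R1.fastq.gz", out / "reads_R2.fastq.gz")
    rd.write_truth_tsv(selected, out / "truth.tsv")
    report.n_pairs = len(pairs)

    # -- mapping ------------------------------------------------------------
    alignments = mp.map_pairs(pairs, plasmid, config.mapper)
    mp.export_sam(alignments, plasmid, out / "aln.sam")
    mapped = [pa.fragment for pa in alignments]
    _analyse(mapped, plasmid, config, out, header, report)
    (out / "report.txt").write_text(report.to_text())
    return report


def run_analysis(
    config: RunConfig,
    plasmid: PlasmidMap,
    sam_path: str | Path,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Analysis-only mode: start from an existing SAM (any aligner)."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"domyseq schema={SCHEMA_VERSION} seed={config.seed} "
        f"config_hash={config.config_hash()} plasmid={plasmid.config_hash()}"
    ]
    report = RunReport(seed=config.seed, config_hash=config.config_hash())
    mapped = mp.import_sam(sam_path, plasmid, config.mapper)
    report.n_pairs = len(mapped)
    _analyse(mapped, plasmid, config, out, header, report)
    (out / "report.txt").write_text(report.to_text())
    return report


def _analyse(
    mapped: list[mp.MappedFragment],
    plasmid: PlasmidMap,
    config: RunConfig,
    out: Path,
    header: list[str],
    report: RunReport,
) -> None:
    """Shared back half: dedup, frames, coverage, plateau call, TAD audit."""
    if not report.n_pairs:
        report.n_pairs = len(mapped)
    report.n_mapped = sum(1 for f in mapped if f.status != "unmapped")
    proper = [f for f in mapped if f.status == "proper_pair"]
    report.n_proper = len(proper)
    unique = mp.dedup(mapped, plasmid.length)
    report.n_unique_pe = len(unique)
    for f in proper:
        cov.decide_frame(f, plasmid)
    if unique:
        dist = cov.frame_distribution(unique)
        dist.to_tsv(out / "frames.tsv", header)
        report.frame_counts = dist.counts
        report.frame_mean_pct = dist.mean_pct
        report.frame_sd_pct = dist.sd_pct
    inframe = cov.filter_inframe(unique, plasmid)
    report.n_inframe = len(inframe)

    strata = {"all": proper, "unique": unique, "inframe": inframe}
    mode_name = {"all": "All", "unique": "UniquePE", "inframe": "InFrame"}
    tracks = {}
    for key, frags in strata.items():
        for space in ("nt", "aa"):
            track = cov.coverage_track(frags, mode_name[key], space, plasmid)
            cov.write_bedgraph(track, out / f"coverage_{key}.{space}.bedgraph", header)
            tracks[(key, space)] = track

    tad_hits = tad_mod.scan_orf(plasmid) + tad_mod.scan_plasmid_frames(plasmid)
    tad_mod.write_hits_tsv(tad_hits, out / "tad_hits.tsv", header)
    report.tad_hits = tad_hits

    call = None
    inframe_aa = tracks[("inframe", "aa")]
    if inframe_aa.values.max(initial=0) > 0:
        call = caller_mod.call_plateau(
            inframe_aa,
            tau=config.caller.tau,
            secondary_floor=config.caller.secondary_floor,
            min_secondary_run=config.caller.min_secondary_run,
        )
        tad_mod.annotate_calls_with_tads(call, tad_hits)
    caller_mod.report_calls(call, plasmid.name, out / "calls.tsv", header)
    report.call = call
    report.validate_funnel()
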