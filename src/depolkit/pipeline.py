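"""End-to-end orchestration and the comparative report.

``run_resurrection`` chains prune -> (consensus | ASR) -> reverse-translate
and writes FASTA/TSV artifacts plus a run log.  ``run_comparison_report``
computes every derived fold change, percent comparison and coupling
stoichiometry from a populated rate table; missing labels are listed but do
not abort the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .asr import ancestral_sequence, reconstruct
from .consensus import consensus_sequence, write_consensus_table
from .errors import ConfigError, DataError
from .kinetics import (
    FoldChange,
    GeometryConstants,
    RateTable,
    fold_change,
    tubulins_per_atp,
)
from .model import build_wag
from .revtrans import read_codon_table, load_sf9_table, reverse_translate
from .seqio import (
    ProteinAlignment,
    prune_to_taxa,
    read_alignment,
    read_tree,
    write_alignment,
)


@dataclass
class RunConfig:
    """Declarative configuration for a full resurrection run."""

    alignment: str
    tree: str
    out_dir: str
    codon_table: str | None = None  # default: packaged Sf9 table
    keep_taxa: list[str] | None = None
    node: str = "root"
    frequencies_mode: str = "model"
    gamma_classes: int | None = None
    gamma_alpha: float = 1.0
    presence_threshold: float = 0.5
    revtrans_mode: str = "top"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__}, fh
            )

    def validate(self) -> None:
        for key in ("alignment", "tree"):
            p = getattr(self, key)
            if not Path(p).is_file():
                raise ConfigError(f"{key} file not found: {p}")
        if self.codon_table and not Path(self.codon_table).is_file():
            raise ConfigError(f"codon_table file not found: {self.codon_table}")
        if not 0.0 <= self.presence_threshold <= 1.0:
            raise ConfigError("presence_threshold must be in [0, 1]")


@dataclass
class ResurrectionOutputs:
    consensus_fasta: Path
    ancestral_fasta: Path
    posterior_tsv: Path
    coding_fasta: Path
    run_log: Path
    log_likelihood: float
    ancestral: str
    consensus: str


def run_resurrection(config: RunConfig) -> ResurrectionOutputs:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    aln = read_alignment(config.alignment)
    tree = read_tree(config.tree)
    if config.keep_taxa:
        tree = prune_to_taxa(tree, config.keep_taxa)
        aln = aln.subset([n for n in aln.names if n in set(config.keep_taxa)])

    model = build_wag(config.frequencies_mode, aln)
    cons = consensus_sequence(aln)
    recon = reconstruct(
        tree,
        model,
        aln,
        gamma_classes=config.gamma_classes,
        gamma_alpha=config.gamma_alpha,
    )
    anc = ancestral_sequence(recon, config.node, config.presence_threshold)
    table = (
        read_codon_table(config.codon_table)
        if config.codon_table
        else load_sf9_table()
    )
    dna = reverse_translate(anc, table, mode=config.revtrans_mode, seed=config.seed)

    consensus_fasta = out / "consensus.fasta"
    ancestral_fasta = out / "ancestral.fasta"
    posterior_tsv = out / "ancestral_posteriors.tsv"
    coding_fasta = out / "ancestral_cds.fasta"
    run_log = out / "run.log"

    write_alignment(ProteinAlignment(["consensus"], [cons.sequence]), consensus_fasta)
    write_consensus_table(cons, out / "consensus_columns.tsv")
    write_alignment(ProteinAlignment([f"ancestral_{config.node}"], [anc]), ancestral_fasta)
    _write_posterior_tsv(recon, config.node, posterior_tsv)
    write_alignment(
        ProteinAlignment([f"ancestral_{config.node}_cds"], [dna]), coding_fasta
    )
    run_log.write_text(
        json.dumps(
            {
                "tool_version": __version__,
                "model": "WAG",
                "frequencies_mode": config.frequencies_mode,
                "gamma_classes": config.gamma_classes,
                "gamma_alpha": config.gamma_alpha,
                "presence_threshold": config.presence_threshold,
                "seed": config.seed,
                "log_likelihood": recon.log_likelihood,
                "n_sequences": aln.nrow,
                "n_columns": aln.ncol,
                "ancestral_length": len(anc),
                "consensus_length": len(cons.sequence),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return ResurrectionOutputs(
        consensus_fasta,
        ancestral_fasta,
        posterior_tsv,
        coding_fasta,
        run_log,
        recon.log_likelihood,
        anc,
        cons.sequence,
    )


def _write_posterior_tsv(recon, node: str, path: Path) -> None:
    from .seqio import AA_ALPHABET

    uid = recon.node_uid(node)
    post = recon.residue_posteriors[uid]
    presence = recon.presence_posteriors[uid]
    with open(path, "w") as fh:
        fh.write("column\tresidue\tprobability\tpresence_posterior\n")
        for j in range(post.shape[0]):
            top = post[j].argsort()[::-1][:3]
            for i in top:
                fh.write(
                    f"{j + 1}\t{AA_ALPHABET[i]}\t{post[j, i]:.6f}"
                    f"\t{presence[j]:.6f}\n"
                )


# ---------------------------------------------------------------------------
# Comparative report
# ---------------------------------------------------------------------------

#: derived quantities emitted by the report: name -> (kind, labels)
REPORT_SPEC: list[tuple[str, str, tuple[str, ...]]] = [
    ("depol_fold_anc13_vs_mcak", "fold", ("depol/Anc13", "depol/MCAK")),
    ("depol_fold_anc13_vs_mcak_egfp", "fold", ("depol/Anc13", "depol/MCAK-EGFP")),
    ("depol_fold_mcak_anc13_vs_mcak", "fold", ("depol/MCAK-Anc13", "depol/MCAK")),
    ("depol_fold_anc13_taxol_vs_basal", "fold", ("depol/Anc13+taxol", "depol/basal")),
    ("depol_fold_anc13_vs_anc13_adp", "fold", ("depol/Anc13", "depol/Anc13+ADP")),
    ("depol_fold_mcak_vs_anc13_adp", "fold", ("depol/MCAK", "depol/Anc13+ADP")),
    ("depol_pct_anc13_taxol_of_mcak", "percent", ("depol/Anc13+taxol", "depol/MCAK")),
    ("depol_pct_con13_of_mcak", "percent", ("depol/Con13", "depol/MCAK")),
    ("depol_pct_con13_of_mcak_egfp", "percent", ("depol/Con13", "depol/MCAK-EGFP")),
    ("koff_ratio_lattice_end_anc13", "fold", ("koff_lattice/Anc13", "koff_end/Anc13")),
    ("koff_ratio_lattice_end_mcak", "fold", ("koff_lattice/MCAK", "koff_end/MCAK")),
    ("kon_fold_anc13_vs_mcak", "fold", ("kon/Anc13", "kon/MCAK")),
    ("atpase_fold_anc13_basal_vs_mcak_basal", "fold", ("atpase_basal/Anc13", "atpase_basal/MCAK")),
    ("atpase_fold_anc13_tubulin_vs_basal", "fold", ("atpase_tubulin/Anc13", "atpase_basal/Anc13")),
    ("atpase_fold_anc13_mt_vs_basal", "fold", ("atpase_mt/Anc13", "atpase_basal/Anc13")),
    ("atpase_fold_mcak_mt_vs_basal", "fold", ("atpase_mt/MCAK", "atpase_basal/MCAK")),
    (
        "tubulins_per_atp_vs_mcak",
        "stoichiometry",
        ("depol/Anc13", "atpase_mt/Anc13", "depol/MCAK", "atpase_mt/MCAK"),
    ),
    (
        "tubulins_per_atp_vs_mcak_egfp",
        "stoichiometry",
        ("depol/Anc13", "atpase_mt/Anc13", "depol/MCAK-EGFP", "atpase_mt/MCAK"),
    ),
]


@dataclass
class ComparisonReport:
    values: dict[str, float]
    uncertainties: dict[str, float]
    missing: dict[str, list[str]]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("quantity\tvalue\tse\n")
            for name, v in self.values.items():
                fh.write(f"{name}\t{v!r}\t{self.uncertainties[name]!r}\n")

    def to_text(self) -> str:
        lines = ["comparative report", "=" * 18]
        for name, v in self.values.items():
            lines.append(f"{name:42s} {v:10.4g} +/- {self.uncertainties[name]:.3g}")
        for name, labels in self.missing.items():
            lines.append(f"{name:42s} SKIPPED (missing {', '.join(labels)})")
        return "\n".join(lines)


def load_reference_rates() -> RateTable:
    """The packaged reference measurement table used by the report layer."""
    path = resources.files("depolkit.data").joinpath("reference_rates.tsv")
    with resources.as_file(path) as p:
        return RateTable.from_tsv(p)


def run_comparison_report(
    rates: RateTable, geometry: GeometryConstants | None = None
) -> ComparisonReport:
    values: dict[str, float] = {}
    errs: dict[str, float] = {}
    missing: dict[str, list[str]] = {}
    for name, kind, labels in REPORT_SPEC:
        absent = [l for l in labels if l not in rates]
        if absent:
            missing[name] = absent
            continue
        if kind == "fold":
            fc: FoldChange = fold_change(rates, labels[0], labels[1])
            values[name], errs[name] = fc.ratio, fc.se
        elif kind == "percent":
            fc = fold_change(rates, labels[0], labels[1])
            values[name], errs[name] = fc.ratio * 100.0, fc.se * 100.0
        elif kind == "stoichiometry":
            st = tubulins_per_atp(
                rates,
                geometry,
                target_depol=labels[0],
                target_atpase=labels[1],
                comparator_depol=labels[2],
                comparator_atpase=labels[3],
            )
            values[name], errs[name] = st.tubulins_per_atp, st.se
        else:  # pragma: no cover
            raise DataError(f"unknown report kind {kind!r}")
    return ComparisonReport(values, errs, missing)
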