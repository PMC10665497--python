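"""Virtual gene panels for the tier-1 (NICU/African) and tier-3 (DDG2P) filters.

A panel is a named set of gene symbols, optionally carrying a founder-variant
subset (genes whose disease alleles are common enough in African populations
to fail naive frequency filters) and a per-gene Mendelian inheritance mode
used by the zygosity-consistency check.

Panels are matched by gene symbol only; symbol aliasing is out of scope, so
panel files must use the same symbol vocabulary as the annotation source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError

logger = logging.getLogger(__name__)

_TRUE_FLAGS = {"1", "true", "yes", "y", "founder"}
_FALSE_FLAGS = {"0", "false", "no", "n", ""}

INHERITANCE_MODES = ("autosomal_dominant", "autosomal_recessive", "x_linked_recessive")

_MODE_ALIASES = {
    "ad": "autosomal_dominant",
    "autosomal_dominant": "autosomal_dominant",
    "ar": "autosomal_recessive",
    "autosomal_recessive": "autosomal_recessive",
    "xlr": "x_linked_recessive",
    "x_linked_recessive": "x_linked_recessive",
}


@dataclass(frozen=True)
class GenePanel:
    """A named, case-normalized set of gene symbols.

    ``inheritance_modes`` maps a subset of ``genes`` to one of
    autosomal_dominant / autosomal_recessive / x_linked_recessive; genes
    without an entry are evaluated under all modes downstream.
    """

    name: str
    genes: frozenset[str]
    founder_variant_genes: frozenset[str] = frozenset()
    inheritance_modes: dict[str, str] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")
        if not self.founder_variant_genes <= self.genes:
            extra = self.founder_variant_genes - self.genes
            raise ValueError(f"founder genes not in panel {self.name!r}: {sorted(extra)}")
        for gene, mode in self.inheritance_modes.items():
            if mode not in INHERITANCE_MODES:
                raise ValueError(f"unknown inheritance mode {mode!r} for {gene}")

    def __len__(self) -> int:
        return len(self.genes)

    def contains(self, gene_symbol: str) -> bool:
        """Case-insensitive membership test."""
        return gene_symbol.upper() in self.genes

    def is_founder_gene(self, gene_symbol: str) -> bool:
        return gene_symbol.upper() in self.founder_variant_genes

    def write(self, path: str | Path) -> None:
        """Serialize as a TSV (symbol, founder flag, inheritance mode)."""
        with open(path, "w") as fh:
            fh.write("gene\tfounder\tinheritance_mode\n")
            for gene in sorted(self.genes):
                founder = "1" if gene in self.founder_variant_genes else "0"
                mode = self.inheritance_modes.get(gene, "")
                fh.write(f"{gene}\t{founder}\t{mode}\n")


def load_panel(path: str | Path, name: str, version: str = "unversioned") -> GenePanel:
    """Load a gene panel from a plain-text list or a TSV metadata table.

    Accepted layouts (``#`` lines and a header line are skipped):

    * one gene symbol per line;
    * two columns: symbol, founder flag (1/0, true/false, yes/no);
    * three columns: symbol, founder flag, inheritance mode (AD/AR/XLR or
      spelled out).

    Symbols are upper-cased and deduplicated; duplicate count is logged.
    """
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InputError(f"cannot read panel file {path}: {exc}") from exc

    genes: set[str] = set()
    founder: set[str] = set()
    modes: dict[str, str] = {}
    n_rows = 0
    n_dups = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        symbol = parts[0].strip().upper()
        if lineno == 1 and symbol in ("GENE", "SYMBOL", "GENE_SYMBOL"):
            continue  # header row
        n_rows += 1
        if symbol in genes:
            n_dups += 1
        genes.add(symbol)
        if len(parts) >= 2:
            flag = parts[1].strip().lower()
            if flag in _TRUE_FLAGS:
                founder.add(symbol)
            elif flag not in _FALSE_FLAGS:
                raise InputError(
                    f"{path}:{lineno}: malformed founder flag {parts[1]!r}"
                )
        if len(parts) >= 3 and parts[2].strip():
            raw_mode = parts[2].strip().lower()
            mode = _MODE_ALIASES.get(raw_mode)
            if mode is None:
                raise InputError(
                    f"{path}:{lineno}: unknown inheritance mode {parts[2]!r}"
                )
            modes[symbol] = mode

    if not genes:
        raise InputError(f"panel file {path} contains no gene symbols")
    if n_dups:
        logger.warning("panel %s: removed %d duplicate symbol(s)", name, n_dups)
    logger.info("panel %s: %d genes loaded from %s", name, len(genes), path)
    return GenePanel(
        name=name,
        genes=frozenset(genes),
        founder_variant_genes=frozenset(founder),
        inheritance_modes=modes,
        version=version,
    )
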