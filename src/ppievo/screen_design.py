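"""Cross-species Y2H matrix-screen design.

Models the combinatorial universe of a matrix yeast-two-hybrid screen in
which every protein from a multi-species ortholog roster is cloned as four
constructs (bait and prey, each tagged N- and C-terminally) and every
unordered protein pair is tested in up to eight bait x prey configurations.

The default roster mirrors a screen of 11 piRNA-precursor-biogenesis
proteins across five Drosophila species, with Kipferl absent from
D. persimilis and D. virilis (53 proteins, 212 constructs, 308 intra- +
1123 inter-species unique pairs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Species",
    "ProteinEntry",
    "Construct",
    "ProteinPair",
    "Configuration",
    "ScreenDesign",
    "build_roster",
    "enumerate_pairs",
    "enumerate_configurations",
    "default_design_config",
    "roster_table",
    "pair_table",
]

ROLES = ("bait", "prey")
TERMINI = ("N", "C")


@dataclass(frozen=True)
class Species:
    species_id: str
    name: str = ""


@dataclass(frozen=True, order=True)
class ProteinEntry:
    """One ortholog: a gene from one species."""

    gene: str
    species: str

    @property
    def label(self) -> str:
        return f"{self.gene}_{self.species}"


@dataclass(frozen=True)
class Construct:
    """A tagged clone of one protein: bait/prey role, N- or C-terminal tag."""

    protein: ProteinEntry
    role: str  # "bait" | "prey"
    tag_terminus: str  # "N" | "C"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.tag_terminus not in TERMINI:
            raise ValueError(
                f"tag_terminus must be one of {TERMINI}, got {self.tag_terminus!r}"
            )

    @property
    def construct_id(self) -> str:
        return f"{self.protein.label}|{self.role}{self.tag_terminus}"


@dataclass(frozen=True)
class ProteinPair:
    """Unordered protein pair; homotypic (a == b) allowed.

    Members are stored in canonical lexicographic order on (gene, species)
    so that a pair compares and hashes identically regardless of input order.
    """

    a: ProteinEntry
    b: ProteinEntry

    def __post_init__(self) -> None:
        if (self.b.gene, self.b.species) < (self.a.gene, self.a.species):
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def homotypic(self) -> bool:
        return self.a == self.b

    @property
    def scope(self) -> str:
        return "intra" if self.a.species == self.b.species else "inter"

    @property
    def key(self) -> str:
        return f"{self.a.label}--{self.b.label}"


@dataclass(frozen=True)
class Configuration:
    """One bait construct x prey construct combination testing a pair."""

    bait: Construct
    prey: Construct

    def __post_init__(self) -> None:
        if self.bait.role != "bait" or self.prey.role != "prey":
            raise ValueError("Configuration requires a bait and a prey construct")

    @property
    def pair(self) -> ProteinPair:
        return ProteinPair(self.bait.protein, self.prey.protein)

    @property
    def key(self) -> tuple[str, str]:
        return (self.bait.construct_id, self.prey.construct_id)


@dataclass
class ScreenDesign:
    """Roster of species, genes, proteins and constructs plus divergence times."""

    species: list[Species]
    genes: list[str]
    absences: set[tuple[str, str]]  # (gene, species_id)
    divergence_my: pd.DataFrame  # symmetric, zero diagonal, in million years
    proteins: list[ProteinEntry] = field(default_factory=list)
    constructs: list[Construct] = field(default_factory=list)

    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    def has_protein(self, gene: str, species: str) -> bool:
        return (
            gene in self.genes
            and species in self.species_ids
            and (gene, species) not in self.absences
        )

    def constructs_for(self, protein: ProteinEntry, role: str) -> list[Construct]:
        return [c for c in self.constructs if c.protein == protein and c.role == role]

    def construct_by_id(self, construct_id: str) -> Construct:
        for c in self.constructs:
            if c.construct_id == construct_id:
                return c
        raise KeyError(construct_id)

    def divergence(self, sp_a: str, sp_b: str) -> float:
        return float(self.divergence_my.loc[sp_a, sp_b])


def default_design_config() -> dict:
    """Config for the default five-species, 11-gene piRNA-pathway roster.

    Divergence times are approximate literature values (million years):
    Dmel-Dsim 5, melanogaster-subgroup to Dere 13, melanogaster group to
    Dper 30, anything to Dvir 40.
    """
    species = ["Dmel", "Dsim", "Dere", "Dper", "Dvir"]
    genes = [
        "Rhi", "Del", "Cuff", "Kipf", "Moon", "TfIIA-S",
        "Trf2", "CtBP", "Boot", "Nxf3", "UAP56",
    ]
    div = {s: {t: 0.0 for t in species} for s in species}

    def set_d(a: str, b: str, d: float) -> None:
        div[a][b] = d
        div[b][a] = d

    set_d("Dmel", "Dsim", 5.0)
    for s in ("Dmel", "Dsim"):
        set_d(s, "Dere", 13.0)
    for s in ("Dmel", "Dsim", "Dere"):
        set_d(s, "Dper", 30.0)
    for s in ("Dmel", "Dsim", "Dere", "Dper"):
        set_d(s, "Dvir", 40.0)
    return {
        "species": species,
        "genes": genes,
        "absences": [["Kipf", "Dper"], ["Kipf", "Dvir"]],
        "divergence_my": div,
    }


def _validate_divergence(df: pd.DataFrame) -> None:
    if not (df.values == df.values.T).all():
        raise ValueError("divergence matrix must be symmetric")
    if (df.values.diagonal() != 0).any():
        raise ValueError("divergence matrix diagonal must be zero")
    if (df.values < 0).any():
        raise ValueError("divergence times must be non-negative")


def build_roster(config: dict) -> ScreenDesign:
    """Build a :class:`ScreenDesign` from a screen-design config mapping.

    Expected keys: ``species`` (list of ids or ``{species_id, name}``
    mappings), ``genes`` (list of symbols), ``absences`` (list of
    ``[gene, species_id]``), ``divergence_my`` (nested mapping
    species -> species -> My; missing entries default to 0 on the
    diagonal and must otherwise be present).

    The roster expansion is deterministic: proteins are ordered by
    (gene, species) following the config's gene and species order, and
    each protein gets exactly four constructs (bait-N, bait-C, prey-N,
    prey-C).
    """
    raw_species = config.get("species") or []
    if not raw_species:
        raise ValueError("config must list at least one species")
    species: list[Species] = []
    for entry in raw_species:
        if isinstance(entry, str):
            species.append(Species(entry))
        else:
            species.append(Species(entry["species_id"], entry.get("name", "")))
    ids = [s.species_id for s in species]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids in config")

    genes = list(config.get("genes") or [])
    if not genes:
        raise ValueError("config must list at least one gene")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene symbols in config")

    absences: set[tuple[str, str]] = set()
    for gene, sp in config.get("absences", []):
        if gene not in genes:
            raise ValueError(f"absence references unknown gene {gene!r}")
        if sp not in ids:
            raise ValueError(f"absence references unknown species {sp!r}")
        absences.add((gene, sp))

    div_cfg = config.get("divergence_my")
    if div_cfg is not None:
        df = pd.DataFrame(div_cfg).reindex(index=ids, columns=ids).astype(float)
        if df.isna().any().any():
            raise ValueError("divergence_my must cover every species pair")
    else:
        df = pd.DataFrame(0.0, index=ids, columns=ids)
    _validate_divergence(df)

    design = ScreenDesign(species=species, genes=genes, absences=absences,
                          divergence_my=df)
    for gene in genes:
        for sp in ids:
            if (gene, sp) in absences:
                continue
            protein = ProteinEntry(gene, sp)
            design.proteins.append(protein)
            for role in ROLES:
                for term in TERMINI:
                    design.constructs.append(Construct(protein, role, term))
    return design


def enumerate_pairs(design: ScreenDesign) -> list[ProteinPair]:
    """All unique unordered protein pairs, homotypic self-pairs included.

    For P proteins this yields P(P+1)/2 pairs, partitioned into intra-
    (same species) and inter-species pairs via ``ProteinPair.scope``.
    """
    proteins = sorted(design.proteins)
    return [
        ProteinPair(a, b)
        for a, b in itertools.combinations_with_replacement(proteins, 2)
    ]


def enumerate_configurations(
    pair: ProteinPair,
    design: ScreenDesign,
    exclude_auto_active: bool = False,
    auto_active: set[str] | frozenset[str] = frozenset(),
) -> list[Configuration]:
    """All distinct bait x prey configurations testing one protein pair.

    A heterotypic pair yields 8 configurations (2 bait tags x 2 prey tags
    x 2 orientations); a homotypic pair yields 4 (the orientation swap is
    the identity). With ``exclude_auto_active`` set, configurations using
    a construct id listed in ``auto_active`` are dropped.
    """
    for p in (pair.a, pair.b):
        if p not in design.proteins:
            raise ValueError(f"protein {p.label} not in roster")
    configs: list[Configuration] = []
    orientations = [(pair.a, pair.b)]
    if not pair.homotypic:
        orientations.append((pair.b, pair.a))
    for bait_protein, prey_protein in orientations:
        for bait in design.constructs_for(bait_protein, "bait"):
            for prey in design.constructs_for(prey_protein, "prey"):
                configs.append(Configuration(bait, prey))
    if exclude_auto_active:
        configs = [
            c
            for c in configs
            if c.bait.construct_id not in auto_active
            and c.prey.construct_id not in auto_active
        ]
    return configs


def roster_table(design: ScreenDesign) -> pd.DataFrame:
    """Roster expansion as a table (gene, species, construct columns)."""
    return pd.DataFrame(
        [{"gene": p.gene, "species": p.species, "protein": p.label}
         for p in design.proteins]
    )


def pair_table(design: ScreenDesign) -> pd.DataFrame:
    """All unique pairs with scope labels and divergence times."""
    rows = []
    for pair in enumerate_pairs(design):
        rows.append(
            {
                "gene_a": pair.a.gene,
                "species_a": pair.a.species,
                "gene_b": pair.b.gene,
                "species_b": pair.b.species,
                "scope": pair.scope,
                "homotypic": pair.homotypic,
                "divergence_my": design.divergence(pair.a.species, pair.b.species),
            }
        )
    return pd.DataFrame(rows)
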