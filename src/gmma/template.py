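"""Reference amplicon template: coordinates, translation frame, and I/O.

Everything downstream — mutation calling, genotype translation, library
simulation — is defined relative to a :class:`ReferenceTemplate`: the sequenced
amplicon, the window of bases covered by the doped mutagenesis oligos, the two
10-base flanks used for sequencing-error estimation, and the reading frame that
maps window codons to protein residue numbers.

DNA coordinates are 0-based half-open throughout; protein residue numbers are
1-based and anchored at ``protein_offset`` (the residue encoded by the first
full codon in the window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")

#: Standard codon -> one-letter amino acid table; stop codons map to "*".
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
GENETIC_CODE.update({codon: "*" for codon in standard_dna_table.stop_codons})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FLANK_LENGTH = 10


@dataclass(frozen=True)
class ReferenceTemplate:
    """The amplicon reference everything is called against.

    Parameters
    ----------
    dna_sequence
        Upper-case A/C/G/T sequence of the full sequenced amplicon region
        (flank + mutated window + flank).
    window
        Half-open 0-based base interval covered by the doped oligos.
    doped_positions
        Base positions eligible for doping: the window minus fixed cloning-site
        bases (e.g. the USER-cassette bases between the two oligos).
    protein_offset
        1-based residue number of the first full codon in the window.
    frame
        Offset of the first codon start within the window (0, 1 or 2).
    """

    dna_sequence: str
    window: tuple[int, int]
    doped_positions: frozenset[int]
    protein_offset: int = 48
    frame: int = 0
    flank_length: int = FLANK_LENGTH

    def __post_init__(self) -> None:
        seq = self.dna_sequence.upper()
        object.__setattr__(self, "dna_sequence", seq)
        object.__setattr__(self, "doped_positions", frozenset(self.doped_positions))
        if not set(seq) <= DNA_ALPHABET:
            raise ValueError("template sequence must contain only A/C/G/T")
        start, end = self.window
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"window {self.window} outside sequence of length {len(seq)}")
        if start < self.flank_length or end + self.flank_length > len(seq):
            raise ValueError("template must include a full flank on each side of the window")
        if not self.doped_positions <= set(range(start, end)):
            raise ValueError("doped_positions must lie inside the window")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")

    # -- coordinates ---------------------------------------------------------

    @property
    def flanks(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """The two flank intervals immediately up/downstream of the window."""
        start, end = self.window
        return ((start - self.flank_length, start), (end, end + self.flank_length))

    @property
    def window_sequence(self) -> str:
        return self.dna_sequence[self.window[0]:self.window[1]]

    @property
    def n_codons(self) -> int:
        return (self.window[1] - self.window[0] - self.frame) // 3

    def codon_interval(self, codon_index: int) -> tuple[int, int]:
        """Absolute base interval of the ``codon_index``-th full window codon."""
        start = self.window[0] + self.frame + 3 * codon_index
        return (start, start + 3)

    def codon_index_of(self, position: int) -> int:
        """Full-codon index containing an absolute base position.

        Raises ``ValueError`` if the position falls outside a complete codon
        (i.e. in the partial-frame leader or trailer of the window).
        """
        start, end = self.window
        idx = (position - start - self.frame) // 3
        if position < start + self.frame or idx >= self.n_codons:
            raise ValueError(f"base {position} not inside a complete window codon")
        return idx

    def residue_number(self, codon_index: int) -> int:
        return self.protein_offset + codon_index

    def reference_codon(self, codon_index: int) -> str:
        a, b = self.codon_interval(codon_index)
        return self.dna_sequence[a:b]

    def reference_aa(self, residue: int) -> str:
        return GENETIC_CODE[self.reference_codon(residue - self.protein_offset)]

    @property
    def protein_sequence(self) -> str:
        """Translation of the full window codons."""
        a = self.window[0] + self.frame
        return str(Seq(self.dna_sequence[a:a + 3 * self.n_codons]).translate())


def load_template(fasta_path: str | Path, config_path: str | Path) -> ReferenceTemplate:
    """Read a template from a single-record FASTA plus a YAML coordinate config.

    The config holds ``window_start``, ``window_end``, ``protein_offset``,
    ``frame`` and ``undoped_positions`` (absolute base positions inside the
    window excluded from doping, e.g. USER-site bases).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected one FASTA record, found {len(records)}")
    cfg = yaml.safe_load(Path(config_path).read_text())
    start, end = int(cfg["window_start"]), int(cfg["window_end"])
    undoped = set(int(p) for p in cfg.get("undoped_positions", []))
    return ReferenceTemplate(
        dna_sequence=str(records[0].seq),
        window=(start, end),
        doped_positions=frozenset(set(range(start, end)) - undoped),
        protein_offset=int(cfg.get("protein_offset", 48)),
        frame=int(cfg.get("frame", 0)),
        flank_length=int(cfg.get("flank_length", FLANK_LENGTH)),
    )


def save_template(template: ReferenceTemplate, fasta_path: str | Path,
                  config_path: str | Path, name: str = "amplicon") -> None:
    """Write the template as FASTA + YAML config (inverse of :func:`load_template`)."""
    Path(fasta_path).write_text(f">{name}\n{template.dna_sequence}\n")
    start, end = template.window
    cfg = {
        "window_start": start,
        "window_end": end,
        "protein_offset": template.protein_offset,
        "frame": template.frame,
        "flank_length": template.flank_length,
        "undoped_positions": sorted(set(range(start, end)) - template.doped_positions),
    }
    Path(config_path).write_text(yaml.safe_dump(cfg, sort_keys=False))
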