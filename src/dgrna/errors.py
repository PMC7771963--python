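"""Exception hierarchy for the design pipeline.

Every error a batch run can hit is a subclass of :class:`DgrnaError`, so the
CLI can distinguish per-gene failures (reported, run continues) from fatal
input problems.
"""


class DgrnaError(Exception):
    """Base class for all package errors."""


class FastaError(DgrnaError):
    """Malformed FASTA input (empty file, duplicate or illegal records)."""


class GffError(DgrnaError):
    """Malformed GFF3 input (orphan CDS, mixed-strand transcript, ...)."""


class VcfError(DgrnaError):
    """Malformed VCF input or REF/assembly disagreement."""


class CoordinateError(DgrnaError):
    """Interval out of chromosome bounds or otherwise ill-formed."""


class NoCleanRegion(DgrnaError):
    """No target window of at least the minimum length avoids foreign CDS."""

    def __init__(self, gene_id: str, role: str, blocking: tuple[str, ...]):
        self.gene_id = gene_id
        self.role = role
        self.blocking = tuple(blocking)
        names = ", ".join(self.blocking) if self.blocking else "(none found)"
        super().__init__(
            f"no clean {role} window for {gene_id}; blocking CDS from: {names}"
        )


class NoViablePair(DgrnaError):
    """No PASS guide pair satisfies the minimum cut separation."""

    def __init__(self, gene_id: str, stage: str, detail: str = ""):
        self.gene_id = gene_id
        self.stage = stage
        msg = f"no viable guide pair for {gene_id} (failed at: {stage})"
        if detail:
            msg += f" -- {detail}"
        super().__init__(msg)


class MissingWeightError(DgrnaError):
    """Efficiency weight table does not cover a (position, base) cell."""


class PrimerError(DgrnaError):
    """Base class for primer mapping problems."""


class PrimerUnmapped(PrimerError):
    """Primer has no exact match in the template."""


class AmbiguousPrimer(PrimerError):
    """Primer maps to more than one site in the template."""


class PrimerLost(PrimerError):
    """Primer footprint overlaps the deleted interval."""


class DivergentPrimers(PrimerError):
    """Primer pair cannot form an amplicon (wrong chrom/strand/orientation)."""


class FixtureError(DgrnaError):
    """Infeasible synthetic-fixture parameters."""
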