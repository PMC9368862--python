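"""Package-wide exception hierarchy."""


class BsamapError(Exception):
    """Base class for all bsamap errors."""


class FormatError(BsamapError):
    """A file does not conform to the expected format."""


class ConfigurationError(BsamapError):
    """Invalid parameter, sample name, or option combination."""


class GenerationError(BsamapError):
    """The synthetic-data generator could not satisfy its constraints."""


class ConsistencyError(BsamapError):
    """Inputs contradict each other (e.g. VCF REF does not match the genome)."""


class ZeroDepthError(BsamapError):
    """Allele frequencies requested for a pool with no reads."""


class FineMapInconsistencyError(BsamapError):
    """Every candidate region is excluded; suggests phenotyping/genotyping
    error or a wrong inheritance mode."""


class FineMapAmbiguityError(BsamapError):
    """More than one disjoint region remains feasible."""

    def __init__(self, regions):
        self.regions = list(regions)
        super().__init__(
            f"{len(self.regions)} disjoint feasible regions: {self.regions}"
        )
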