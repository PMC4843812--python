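"""Exception and warning types shared across the package."""


class RefstabError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(RefstabError, ValueError):
    """A table file or in-memory table violates the expected structure
    (duplicate gene symbols, missing required columns, bad layout)."""


class CompletenessError(RefstabError, ValueError):
    """A Ct matrix contains missing cells and missing values were not
    explicitly allowed. Carries the offending (gene, sample) pairs."""

    def __init__(self, cells):
        self.cells = list(cells)
        listing = ", ".join(f"({g}, {s})" for g, s in self.cells[:10])
        more = "" if len(self.cells) <= 10 else f" and {len(self.cells) - 10} more"
        super().__init__(f"missing Ct values at {listing}{more}")


class SubsetError(RefstabError, ValueError):
    """A subset selector matched too few samples or an unknown subset name."""


class ReplicateDispersionWarning(UserWarning):
    """Technical replicates of one sample span more than the configured
    number of cycles; the collapsed mean may hide a pipetting problem."""


class AmpliconLengthWarning(UserWarning):
    """An amplicon length falls outside the 100-250 bp design window
    recommended for SYBR-green qPCR assays."""


class NearFloorCtWarning(UserWarning):
    """A Ct value above 40 cycles: the transcript is near the detection
    floor of a standard 40-45 cycle protocol."""
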