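"""Exception hierarchy for poolsplit."""


class PoolsplitError(Exception):
    """Base class for all poolsplit errors."""


class VCFParseError(PoolsplitError):
    """A VCF record could not be parsed."""


class NoInformativeVariantsError(PoolsplitError):
    """Every SNV was removed by filtering.

    Usually means the variant set is dominated by homozygous or noisy
    sites; supplying a common-SNP list for intersection typically helps.
    """


class DenseSubmatrixError(PoolsplitError):
    """Dense-submatrix selection collapsed below the minimum seed size."""


class EmptyClusterError(PoolsplitError):
    """K-means seeding repeatedly produced an empty cluster."""


class IndistinguishableClustersError(PoolsplitError):
    """Some pair of clusters is identical on every NA-free P/A row."""
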