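"""The 25-locus / 7-linkage-group X-STR panel used as the default layout.

Seven physically clustered groups span the X chromosome (hg38): Xp22.31,
Xp21.1, Xq12, Xq21.31, Xq23, Xq26 and Xq28. For each locus the published
coordinates delimit the ~20 kb searched range of flanking SNPs; the locus
itself is represented here as the midpoint of that range with a 10 kb
window on each side, which reproduces the searched span to within the STR's
own length. Nearby loci may have overlapping searched ranges (DXS10134 /
DXS10147); each is still called independently.
"""

from __future__ import annotations

from .iohub import MarkerLocus

# name, searched-range start (bp, hg38), searched-range end, linkage group
_PANEL_RANGES: list[tuple[str, int, int, str]] = [
    ("DXS10135", 9_328_425, 9_348_272, "LG1"),
    ("DXS8378", 9_392_268, 9_412_149, "LG1"),
    ("DXSF02", 9_421_117, 9_441_015, "LG1"),
    ("DXSF07", 35_245_296, 35_259_972, "LG2"),
    ("DXSF08", 35_265_159, 35_280_046, "LG2"),
    ("DXSF09", 35_503_675, 35_523_163, "LG2"),
    ("DXS10079", 67_415_135, 67_506_061, "LG3"),
    ("DXSF13", 67_509_674, 67_529_631, "LG3"),
    ("DXS10074", 67_747_354, 67_767_263, "LG3"),
    ("DXS10075", 67_768_408, 67_788_346, "LG3"),
    ("DXSF15", 87_054_170, 87_074_122, "LG4"),
    ("DXS6803", 87_166_198, 87_186_181, "LG4"),
    ("DXSF18", 87_316_334, 87_336_227, "LG4"),
    ("DXSF19", 87_601_689, 87_621_551, "LG4"),
    ("DXSF28", 115_387_331, 115_407_238, "LG5"),
    ("DXSF29", 115_425_127, 115_444_966, "LG5"),
    ("DXSF33", 116_371_407, 116_391_252, "LG5"),
    ("DXS10103", 134_275_121, 134_294_757, "LG6"),
    ("DXS10102", 134_396_132, 134_416_053, "LG6"),
    ("HPRTB", 134_471_543, 134_491_504, "LG6"),
    ("DXS10101", 134_510_526, 134_530_482, "LG6"),
    ("DXS10146", 150_394_029, 150_413_689, "LG7"),
    ("DXS10134", 150_471_870, 150_491_846, "LG7"),
    ("DXS10147", 150_485_241, 150_505_090, "LG7"),
    ("DXS7423", 150_531_954, 150_552_513, "LG7"),
]

CHROM_X = "chrX"
CHROM_X_LENGTH = 156_040_895  # hg38


def default_panel(window_bp: int = 10_000) -> list[MarkerLocus]:
    """The 25-locus panel as :class:`MarkerLocus` records, sorted by position."""
    loci = []
    for name, lo, hi, lg in _PANEL_RANGES:
        mid = (lo + hi) // 2
        loci.append(
            MarkerLocus(
                name=name,
                chrom=CHROM_X,
                start=mid,
                end=mid,
                linkage_group=lg,
                window_bp=window_bp,
            )
        )
    loci.sort(key=lambda m: m.start)
    return loci


def searched_range(name: str) -> tuple[int, int]:
    """Published searched range (bp, hg38) for a panel locus."""
    for n, lo, hi, _ in _PANEL_RANGES:
        if n == name:
            return (lo, hi)
    raise KeyError(name)
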