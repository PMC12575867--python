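"""Land-cover class schemes.

A :class:`ClassScheme` maps human-readable class labels to the integer codes
stored in classified rasters. The default scheme is the seven-class legend
used throughout the package: forest, shrubland, cropland, built-up, wetland,
waterbody and sparse vegetation.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ClassScheme:
    """Ordered label→code mapping for categorical land-cover rasters.

    Parameters
    ----------
    codes
        Mapping from class label to unique integer code.
    nodata
        Code marking invalid/unobserved pixels; must not collide with a class.
    forest_label
        Which label is "forest" for change accounting.
    """

    codes: dict[str, int]
    nodata: int = 0
    forest_label: str = "forest"

    def __post_init__(self) -> None:
        if len(set(self.codes.values())) != len(self.codes):
            raise ValueError("class codes must be unique")
        if len(self.codes) < 2:
            raise ValueError("a scheme needs at least 2 classes")
        if self.forest_label not in self.codes:
            raise ValueError(f"scheme must contain {self.forest_label!r}")
        if self.nodata in self.codes.values():
            raise ValueError("nodata code collides with a class code")

    @property
    def labels(self) -> list[str]:
        return list(self.codes)

    @property
    def forest_code(self) -> int:
        return self.codes[self.forest_label]

    def label_of(self, code: int) -> str:
        for lab, c in self.codes.items():
            if c == code:
                return lab
        raise KeyError(code)

    def to_dict(self) -> dict:
        return {
            "codes": dict(self.codes),
            "nodata": self.nodata,
            "forest_label": self.forest_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassScheme":
        return cls(
            codes={str(k): int(v) for k, v in d["codes"].items()},
            nodata=int(d.get("nodata", 0)),
            forest_label=str(d.get("forest_label", "forest")),
        )


#: Seven-class legend used by the bundled scenarios and examples.
DEFAULT_SCHEME = ClassScheme(
    codes={
        "forest": 1,
        "shrubland": 2,
        "cropland": 3,
        "built_up": 4,
        "wetland": 5,
        "waterbody": 6,
        "sparse_vegetation": 7,
    },
    nodata=0,
)
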