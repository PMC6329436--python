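"""Laboratory-test schema: the 36 daily ICU lab tests and their ordering panels.

ICU laboratory tests are not ordered one at a time.  A clinician orders a
*panel* (a complete blood count, a blood-gas draw, liver enzymes, ...) and all
member tests arrive — or fail to arrive — together.  This co-ordering induces
block structure in the missingness pattern, which is the structure the rest of
the package exploits.  Tests with no documented co-ordering partners are
modeled as singleton panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["LabSchema", "default_lab_schema", "INDICATOR_PREFIX"]

#: Prefix marking missingness-indicator columns; reserved in test names.
INDICATOR_PREFIX = "I-"

#: The 36 daily laboratory tests, in canonical column order.
DEFAULT_TESTS = (
    "ALT", "ALK", "AST", "pH", "PCO2", "PO2", "BE", "Na", "K", "Cl",
    "HCO3", "AG", "BG", "BUN", "Cr", "WBC", "RBC", "HGB", "HCT", "MCV",
    "MCH", "MCHC", "RDW", "PLT", "MO", "EO", "BA", "LY", "NE", "Lac",
    "Ca", "Mg", "Phos", "PTT", "PT", "TBil",
)

#: Multi-test ordering panels: differential white count, red-cell indices,
#: arterial blood gas, liver enzymes, renal function, serum anions,
#: coagulation.  Every other test forms its own singleton panel.
DEFAULT_MULTI_PANELS = {
    "cbc_diff": ("BA", "MO", "NE", "EO", "LY"),
    "rbc_indices": ("MCHC", "RDW", "MCV", "RBC", "MCH"),
    "blood_gas": ("BE", "PCO2", "PO2"),
    "liver": ("TBil", "ALT", "AST", "ALK"),
    "renal": ("BUN", "Cr"),
    "anion": ("Cl", "HCO3"),
    "coag": ("PTT", "PT"),
}


@dataclass(frozen=True)
class LabSchema:
    """An ordered set of test names partitioned into ordering panels.

    Parameters
    ----------
    test_names
        Ordered tuple of unique short test identifiers.
    panels
        Mapping from panel identifier to the tuple of member tests.  The
        member lists must partition ``test_names``.
    """

    test_names: tuple[str, ...]
    panels: dict[str, tuple[str, ...]]
    panel_of: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = self.test_names
        if len(set(names)) != len(names):
            dupes = sorted({t for t in names if list(names).count(t) > 1})
            raise ValueError(f"duplicate test names: {dupes}")
        for t in names:
            if t.startswith(INDICATOR_PREFIX):
                raise ValueError(
                    f"test name {t!r} uses the reserved prefix {INDICATOR_PREFIX!r}"
                )
        seen: dict[str, str] = {}
        for panel, members in self.panels.items():
            for t in members:
                if t not in names:
                    raise ValueError(f"panel {panel!r} names unknown test {t!r}")
                if t in seen:
                    raise ValueError(
                        f"test {t!r} appears in panels {seen[t]!r} and {panel!r}; "
                        "panels must partition the test set"
                    )
                seen[t] = panel
        missing = [t for t in names if t not in seen]
        if missing:
            raise ValueError(f"tests not covered by any panel: {missing}")
        object.__setattr__(self, "panel_of", seen)

    @property
    def n_tests(self) -> int:
        return len(self.test_names)

    def multi_test_panels(self) -> dict[str, tuple[str, ...]]:
        """Panels with two or more member tests, in panel-name order."""
        return {p: m for p, m in sorted(self.panels.items()) if len(m) > 1}

    def indicator_name(self, test: str) -> str:
        if test not in self.panel_of:
            raise KeyError(f"unknown test {test!r}")
        return INDICATOR_PREFIX + test


def default_lab_schema() -> LabSchema:
    """Return the default 36-test schema with its 7 multi-test panels.

    Deterministic: repeated calls return equal objects with identical
    ordering.
    """
    panels: dict[str, tuple[str, ...]] = {k: v for k, v in DEFAULT_MULTI_PANELS.items()}
    grouped = {t for members in panels.values() for t in members}
    for t in DEFAULT_TESTS:
        if t not in grouped:
            panels[t] = (t,)
    return LabSchema(test_names=DEFAULT_TESTS, panels=panels)
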