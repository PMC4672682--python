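"""The output layer catalog: all 324 released stream-variable bands.

Each entry describes one band of one multiband file: variable code, band
index, unit, integer scale factor, storage datatype and NoData code.  The
catalog is the single source of truth the writers consult, and it mirrors
the released product structure:

* monthly tmin/tmax in average and distance-weighted average (4 x 12),
  aggregated along the water courses of each sub-catchment;
* monthly precipitation in sum and distance-weighted sum (2 x 12), over the
  full sub-catchment;
* 19 hydro-climatic (bioclim) variables in plain and weighted modes (2 x 19);
* elevation and slope in min/max/range/average (2 x 4);
* flow length and flow accumulation (2);
* 12 land-cover class fractions x {min, max, range, average, weighted
  average} (60);
* 92 binary geological-age classes x weighted sum (92);
* 10 soil variables x {min, max, range, average, weighted average} (50);
* 2 quality-control bands (cells filled by the QC procedure; cells removed
  by the manual mask).

Temperatures are stored as integers x10, slope x100, soil pH x10 and the
unitless bioclim ratios (bio3, bio15) x100.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LayerCatalogEntry", "layer_catalog"]


@dataclass(frozen=True)
class LayerCatalogEntry:
    file: str
    band: int
    code: str
    explanation: str
    unit: str
    scale_factor: int
    storage: str
    nodata: float
    category: str
    metric: str
    domain: str


_MONTHS = [f"{m:02d}" for m in range(1, 13)]

_LANDCOVER_CLASSES = [
    "Evergreen/deciduous needleleaf trees",
    "Evergreen broadleaf trees",
    "Deciduous broadleaf trees",
    "Mixed/other trees",
    "Shrubs",
    "Herbaceous vegetation",
    "Cultivated and managed vegetation",
    "Regularly flooded shrub/herbaceous vegetation",
    "Urban/built-up",
    "Snow/ice",
    "Barren lands/sparse vegetation",
    "Open water",
]

_SOIL_VARIABLES = [
    ("Soil organic carbon (ORCDRC)", "[g/kg]", 1),
    ("Soil pH in H2O (PHIHOX)", "pH * 10", 10),
    ("Sand content mass fraction (SNDPPT)", "[%]", 1),
    ("Silt content mass fraction (SLTPPT)", "[%]", 1),
    ("Clay content mass fraction (CLYPPT)", "[%]", 1),
    ("Coarse fragments (>2 mm fraction) volumetric (CFRVOL)", "[%]", 1),
    ("Cation exchange capacity (CEC)", "[cmol/kg]", 1),
    ("Bulk density of the fine earth fraction (BLD)", "[kg/m3]", 1),
    ("Depth to bedrock (R horizon) up to maximum 240 cm (BDRICM)", "[cm]", 1),
    ("Predicted probability of occurence (0-100%) of R horizon (BDRLOG)", "[%]", 1),
]

_GEOLOGY_AGES = [
    "Archean", "Archean, Permian", "Cambrian", "Cambrian, Precambrian",
    "Cambrian, Proterozoic", "Carboniferous", "Carboniferous, Devonian",
    "Carboniferous, Miocene", "Cenozoic", "Cenozoic, Mesozoic", "Cretaceous",
    "Cretaceous, Carboniferous", "Cretaceous, Devonian", "Cretaceous, Jurassic",
    "Cretaceous, Mississippian", "Cretaceous, Paleogene, Neogene",
    "Cretaceous, Permian", "Cretaceous, Tertiary", "Cretaceous, Triassic",
    "Devonian", "Devonian, Cambrian", "Devonian, Ordovician",
    "Devonian, Proterozoic", "Devonian, Silurian",
    "Devonian, Silurian, Ordovician", "Holocene", "Ice", "Jurassic",
    "Jurassic, Cambrian", "Jurassic, Carboniferous", "Jurassic, Devonian",
    "Jurassic, Mississippian", "Jurassic, Ordovician", "Jurassic, Permian",
    "Jurassic, Triassic", "Kimberlite", "Mesozoic", "Mesozoic, Cenozoic",
    "Mesozoic, Paleozoic", "Mesozoic, Palezoic", "Miocene", "Mississippian",
    "Mississippian, Cambrian", "Mississippian, Devonian", "Neogene",
    "Neogene, Paleogene", "Ordovician", "Ordovician, Cambrian",
    "Ordovician, Proterozoic", "Paleogene", "Paleogene, Cretaceous",
    "Paleozoic", "Paleozoic, Mesozoic", "Paleozoic, Precambrian",
    "Paleozoic, Proterozoic", "Pennsylvanian", "Pennsylvanian, Devonian",
    "Pennsylvanian, Mississippian", "Permian", "Permian, Carboniferous",
    "Permian, Devonian", "Permian, Mississippian", "Permian, Pennsylvanian",
    "Permian, Triassic", "Pleistocene", "Pliocene, Quaternary", "Precambrian",
    "Precambrian, Devonian", "Precambrian, Paleozoic", "Proterozoic",
    "Proterozoic, Archean", "Quaternary", "Quaternary, Neogne",
    "Quaternary, Tertiary", "Salt", "Silurian", "Silurian, Cambrian",
    "Silurian, Ordovician", "Silurian, Proterozoic", "Tertiary",
    "Tertiary, Cretaceous", "Triassic", "Triassic, Carboniferous",
    "Triassic, Devonian", "Triassic, Mississippian", "Triassic, Ordovician",
    "Triassic, Paleozoic", "Triassic, Pennsylvanian", "Triassic, Permian",
    "Triassic, Proterozoic", "Unknown", "Water",
]

_MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June", "July",
    "August", "September", "October", "November", "December",
]


def layer_catalog() -> list[LayerCatalogEntry]:
    """Enumerate all 324 output bands with their storage schema."""
    entries: list[LayerCatalogEntry] = []

    def add(file, band, code, explanation, unit, scale, storage, nodata,
            category, metric, domain):
        entries.append(LayerCatalogEntry(
            file=file, band=band, code=code, explanation=explanation,
            unit=unit, scale_factor=scale, storage=storage, nodata=nodata,
            category=category, metric=metric, domain=domain,
        ))

    # --- topography ------------------------------------------------------
    for band, m in enumerate(("min", "max", "range", "avg"), start=1):
        metric = {"min": "min", "max": "max", "range": "range", "avg": "average"}[m]
        add("elevation.nc", band, f"dem_{m}",
            f"{metric.capitalize()} elevation across sub-catchment",
            "[m]", 1, "Int32", -999, "Topography", metric, "catchment")
    for band, m in enumerate(("min", "max", "range", "avg"), start=1):
        metric = {"min": "min", "max": "max", "range": "range", "avg": "average"}[m]
        add("slope.nc", band, f"slope_{m}",
            f"{metric.capitalize()} slope across sub-catchment",
            "[deg] * 100", 100, "Int32", -999, "Topography", metric, "catchment")
    add("flow_acc.nc", 1, "flow_length",
        "Flow length (number of upstream stream grid cells)",
        "count", 1, "Int32", -999, "Topography", "sum", "watercourse")
    add("flow_acc.nc", 2, "flow_acc",
        "Flow accumulation (total number of upstream grid cells)",
        "count", 1, "Int32", -999, "Topography", "sum", "catchment")

    # --- monthly climate -------------------------------------------------
    for var, vname in (("tmin", "minimum"), ("tmax", "maximum")):
        for metric, mcode in (("average", "avg"), ("weighted_average", "wavg")):
            fname = (f"monthly_{var}_average.nc" if metric == "average"
                     else f"monthly_{var}_weighted_average.nc")
            word = "Average" if metric == "average" else "Weighted average"
            for band, mm in enumerate(_MONTHS, start=1):
                add(fname, band, f"{var}_{mcode}_{mm}",
                    f"{word} {vname} monthly air temperature across water "
                    f"courses in sub-catchment for {_MONTH_NAMES[band - 1]}",
                    "[degC] * 10", 10, "Int32", -999,
                    "Climate", metric, "watercourse")
    for metric, mcode, fname, word in (
        ("sum", "sum", "monthly_prec_sum.nc", "Sum of"),
        ("weighted_sum", "wsum", "monthly_prec_weighted_sum.nc", "Weighted sum of"),
    ):
        for band, mm in enumerate(_MONTHS, start=1):
            add(fname, band, f"prec_{mcode}_{mm}",
                f"{word} monthly precipitation across the sub-catchment "
                f"for {_MONTH_NAMES[band - 1]}",
                "[mm]", 1, "Float64", -9999,
                "Climate", metric, "catchment")

    # --- hydro-climatic (bioclim) ----------------------------------------
    for mode, mcode, fname in (
        ("plain", "avg", "hydroclim_average+sum.nc"),
        ("weighted", "wavg", "hydroclim_weighted_average+sum.nc"),
    ):
        for b in range(1, 20):
            temperature_based = b <= 11
            if b == 3:
                unit, scale = "* 100", 100
            elif b == 15:
                unit, scale = "* 100", 100
            elif temperature_based:
                unit, scale = "[degC] * 10", 10
            else:
                unit, scale = "[mm]", 1
            storage = "Int32" if temperature_based else "Float64"
            metric = (
                ("average" if mode == "plain" else "weighted_average")
                if temperature_based
                else ("sum" if mode == "plain" else "weighted_sum")
            )
            domain = "watercourse" if temperature_based else "catchment"
            scope = ("across sub-catchment (water courses only)"
                     if temperature_based else "across sub-catchment")
            word = "average" if mode == "plain" else "weighted average"
            add(fname, b, f"hydro_{mcode}_{b:02d}",
                f"Bioclim {b}, {word} {scope}",
                unit, scale, storage, -9999, "Climate", metric, domain)

    # --- land cover ------------------------------------------------------
    for metric, mcode, fword in (
        ("min", "min", "minimum"), ("max", "max", "maximum"),
        ("range", "range", "range"), ("average", "avg", "average"),
        ("weighted_average", "wavg", "weighted_average"),
    ):
        pretty = fword.replace("_", " ")
        for band, cls in enumerate(_LANDCOVER_CLASSES, start=1):
            add(f"landcover_{fword}.nc", band, f"lc_{mcode}_{band:02d}",
                f"{cls}, {pretty} across sub-catchment",
                "[%]", 1, "Byte", -127, "Land cover", metric, "catchment")

    # --- surface geology -------------------------------------------------
    for band, age in enumerate(_GEOLOGY_AGES, start=1):
        add("geology_weighted_sum.nc", band, f"geo_wsum_{band:02d}",
            f"{age} geology across sub-catchment",
            "weighted count", 1, "Int32", -9999,
            "Surface geology", "weighted_sum", "catchment")

    # --- soil ------------------------------------------------------------
    for metric, mcode, fword in (
        ("min", "min", "minimum"), ("max", "max", "maximum"),
        ("range", "range", "range"), ("average", "avg", "average"),
        ("weighted_average", "wavg", "weighted_average"),
    ):
        for band, (name, unit, scale) in enumerate(_SOIL_VARIABLES, start=1):
            add(f"soil_{fword}.nc", band, f"soil_{mcode}_{band:02d}",
                f"{name} across sub-catchment",
                unit, scale, "Int32", -999, "Soil", metric, "catchment")

    # --- quality control -------------------------------------------------
    add("quality_control.nc", 1, "missing_cells",
        "Cells that were filled based on the maximum neighbour value",
        "-", 1, "Byte", -127, "Quality control", "-", "-")
    add("quality_control.nc", 2, "cells_removed",
        "Cells that were removed manually",
        "-", 1, "Byte", -127, "Quality control", "-", "-")

    return entries
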