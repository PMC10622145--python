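"""Build an ICMS motor map: Voronoi tiles, M1 border, forelimb mask.

Stimulation sites carry evoked-movement labels and current thresholds.
Classes are consolidated (digits/wrist -> hand, shoulder/elbow -> arm),
tiles are Voronoi cells clipped to a 0.75-mm radius, and the M1 rostral
border separates low-threshold (<30 uA) from high-threshold sites 3-5 mm
from the central sulcus.
"""

from collections import Counter

from shapely.geometry import LineString

from isoimap import SimConfig, simulate
from isoimap.motormap import (MotorMap, delineate_m1_border,
                              rasterize_forelimb_mask)

cfg = SimConfig(seed=11)
sites = simulate.gen_motor_sites(cfg, 11)
print(f"{len(sites.drop_duplicates(['x_mm', 'y_mm']))} penetrations "
      f"({len(sites)} site-movement rows)")

mmap = MotorMap.from_site_table(
    sites[["x_mm", "y_mm", "joint", "movement", "threshold_uA"]],
    bounds=(0, 0, 12.8, 12.8),
)
print("consolidated classes:", dict(Counter(mmap.consolidated_class)))

cs = LineString([(0, 0), (0, 12.8)])  # central sulcus along the caudal edge
out = delineate_m1_border(mmap, cs, pm_divide_y_mm=9.0)
print("area labels:", dict(Counter(out["area"])))
print(f"border polyline: {len(out['border_mm'])} vertices; "
      f"{len(out['band_violations'])} outside the 3-5 mm band")

fm = rasterize_forelimb_mask(mmap, cfg.geometry)
for area, mask in fm.per_area.items():
    print(f"  {area} forelimb: {mask.sum()} px")
print(f"combined forelimb representation: {fm.n_countable} px")
print("\nThe forelimb mask (hand + arm + dual tiles in M1 and PMd; PMv and")
print("face/trunk excluded) is the denominator for all overlap percentages.")
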