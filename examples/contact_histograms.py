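"""Surface-separation histograms distinguish contact from intrusion.

Two spheres that merely touch and two spheres where one intrudes into an
invagination of the other can look identical in single slices.  The
area-weighted distance histogram separates them: intrusion puts a large
share of the host's surface within the first 5-nm bracket.
"""

from voxtract.grid import VoxelGrid
from voxtract.meshing import marching_cubes
from voxtract.interactome import surface_distance, surface_histogram, closest_approach
from voxtract.synthetic import intruded_spheres

for mode in ("tangent", "intruded"):
    s1, s2, spacing = intruded_spheres(diameter_vox=64, mode=mode,
                                       intrusion_depth_nm=50.0)
    m1 = marching_cubes(VoxelGrid(s1.astype("uint8") * 255, spacing=spacing), 127.5)
    m2 = marching_cubes(VoxelGrid(s2.astype("uint8") * 255, spacing=spacing), 127.5)
    dm = surface_distance(m1, m2)  # host surface vs intruder
    hist = surface_histogram(dm)
    print(f"{mode}: closest approach {closest_approach(dm):.2f} nm")
    print("  % of host surface per separation bracket (first 6 bins):")
    for label, row in hist.head(6).iterrows():
        bar = "#" * int(round(row.area_percent))
        print(f"  {label:>9} {row.area_percent:6.2f}%  {bar}")
    print()

print("The intruded geometry concentrates host surface area in the 0-5 nm")
print("bracket; mere tangency leaves it spread over larger separations.")
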