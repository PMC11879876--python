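"""Two-channel colocalization: the pixelwise product map.

Generates synthetic red/green channel pairs at several interpenetration
fractions and quantifies mixing by <I_y> with I_y = I_r * I_g, the
observable used to detect interpenetrated A/B nanostar networks in
two-colour images.
"""

from nanolink.imaging import ChannelImage, yellow_map
from nanolink.synthetic import make_two_channel_image

print("phi (constructed)   <I_y> (measured)")
for phi in (0.0, 0.25, 0.5, 0.75, 1.0):
    red, green, expected = make_two_channel_image((256, 256), phi, seed=4)
    _, mean, sd = yellow_map(ChannelImage(red), ChannelImage(green))
    print(f"      {phi:4.2f}             {mean:5.3f} +- {sd:5.3f}")

print(
    "\n<I_y> rises linearly with the co-occupied area fraction: ~0 for "
    "fully demixed phases, large for interpenetrated ones, so the product "
    "map is a direct interpenetration readout."
)
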