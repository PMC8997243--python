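"""Convert pixel tracks to metric units with a marked reference object.

A rectangular arena of known physical size (24.9 cm x 11.4 cm) imaged at
498 x 228 px fixes the scale; the designated corner becomes the world
origin.  The same scale applied to a tracked displacement converts px/s to
m/s.
"""

from contourpose import build_calibration, to_world

corners = [[75, 60], [573, 60], [573, 288], [75, 288]]
cal = build_calibration("rectangle", corners, (0.249, 0.114))
print(f"scale      : {cal.scale:.3e} m/px "
      f"(side estimates disagree by {cal.side_disagreement:.2%})")
print(f"origin     : pixel ({cal.origin_px[0]:.0f}, {cal.origin_px[1]:.0f}) "
      f"-> (0, 0) m")

track_px = [[100, 80], [150, 80], [200, 120]]
track_m = to_world(track_px, cal)
for p, w in zip(track_px, track_m):
    print(f"  {p} px -> ({w[0]*100:.2f}, {w[1]*100:.2f}) cm")
speed_px_s = 120.0
print(f"a speed of {speed_px_s:.0f} px/s is "
      f"{speed_px_s * cal.scale * 100:.1f} cm/s in this arena")
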