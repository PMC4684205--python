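"""Build the procedural swimmer body and inspect its mass properties.

Generates the 3.35 m four-flippered swimmer (rigid torso incl. head, neck
and tail, plus four cambered hydrofoil flippers), checks watertightness and
prints per-link masses at fluid density (the body is neutrally buoyant).
"""

from plesioswim.geometry import BodySpec, build_swimmer

for bulk in (1.0, 1.5):
    body = build_swimmer(BodySpec(muscle_bulk_factor=bulk))
    label = "slim" if bulk == 1.0 else "bulky (+50% girdle muscle)"
    print(f"\n{label}: total mass {body.total_mass:.1f} kg")
    for name, link in body.links.items():
        mesh = link.mesh
        print(f"  {name:12s} mass {link.mass:7.2f} kg  "
              f"volume {mesh.volume * 1e3:7.2f} L  watertight={mesh.is_watertight}")

# The slim/bulky difference sits in the torso (limb-girdle soft tissue);
# the flipper planforms are identical between the two variants.
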