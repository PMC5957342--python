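# Default toy binding sites and species.
#
# Values are illustrative model parameters chosen to realize the physical
# regimes the package studies (a water-friendly pocket that repels anions,
# a carbonyl cage that holds a cation, and bulk "hydration shell"
# environments that give ions a large desolvation penalty).  They are not
# fitted to any force field.
#
# Units: nm, kJ/mol, elementary charges, g/mol.

species:
  toy_water:
    charge: 0.0
    lj_epsilon: 4.0
    lj_sigma: 0.28
    mass: 18.0
  toy_fluoride:
    charge: -1.0
    lj_epsilon: 0.8
    lj_sigma: 0.30
    mass: 19.0
  toy_sodium:
    charge: 1.0
    lj_epsilon: 0.3
    lj_sigma: 0.25
    mass: 23.0

sites:
  # Three H-bond-donor-like centers in a plane ("F85-like" pocket):
  # attractive LJ contacts for a water-sized neutral particle, small
  # negative partial charges that repel an anion.
  f85_like:
    dielectric: 4.0
    cage_k: 0.0
    site_center: [0.0, 0.0, 0.0]
    escape_radius: 0.55
    box_halfwidth: 0.8
    centers:
      - {position: [0.0, 0.33, 0.0], charge: -0.10, lj_epsilon: 9.0, lj_sigma: 0.30}
      - {position: [-0.2858, -0.165, 0.0], charge: -0.10, lj_epsilon: 9.0, lj_sigma: 0.30}
      - {position: [0.2858, -0.165, 0.0], charge: -0.10, lj_epsilon: 9.0, lj_sigma: 0.30}

  # Tetrahedral four-carbonyl-like cage ("TM3-like"): strong cation
  # coordination, only mild LJ contacts for water.
  tm3_like:
    dielectric: 4.0
    cage_k: 0.0
    site_center: [0.0, 0.0, 0.0]
    escape_radius: 0.55
    box_halfwidth: 0.8
    centers:
      - {position: [0.1617, 0.1617, 0.1617], charge: -0.12, lj_epsilon: 1.0, lj_sigma: 0.30}
      - {position: [0.1617, -0.1617, -0.1617], charge: -0.12, lj_epsilon: 1.0, lj_sigma: 0.30}
      - {position: [-0.1617, 0.1617, -0.1617], charge: -0.12, lj_epsilon: 1.0, lj_sigma: 0.30}
      - {position: [-0.1617, -0.1617, 0.1617], charge: -0.12, lj_epsilon: 1.0, lj_sigma: 0.30}

  # Implicit "bulk solvent" for an anion: a tetrahedral shell of positive
  # partial charges whose loss on decoupling is the toy's desolvation
  # penalty.  Water feels only weak LJ contacts here.
  bulk_shell:
    dielectric: 4.0
    cage_k: 0.0
    site_center: [0.0, 0.0, 0.0]
    escape_radius: 0.55
    box_halfwidth: 0.8
    centers:
      - {position: [0.1732, 0.1732, 0.1732], charge: 0.125, lj_epsilon: 0.4, lj_sigma: 0.28}
      - {position: [0.1732, -0.1732, -0.1732], charge: 0.125, lj_epsilon: 0.4, lj_sigma: 0.28}
      - {position: [-0.1732, 0.1732, -0.1732], charge: 0.125, lj_epsilon: 0.4, lj_sigma: 0.28}
      - {position: [-0.1732, -0.1732, 0.1732], charge: 0.125, lj_epsilon: 0.4, lj_sigma: 0.28}

  # Mirror shell for cations (used by the TM3-like demo).
  bulk_cation_shell:
    dielectric: 4.0
    cage_k: 0.0
    site_center: [0.0, 0.0, 0.0]
    escape_radius: 0.55
    box_halfwidth: 0.8
    centers:
      - {position: [0.1732, 0.1732, 0.1732], charge: -0.125, lj_epsilon: 0.4, lj_sigma: 0.28}
      - {position: [0.1732, -0.1732, -0.1732], charge: -0.125, lj_epsilon: 0.4, lj_sigma: 0.28}
      - {position: [-0.1732, 0.1732, -0.1732], charge: -0.125, lj_epsilon: 0.4, lj_sigma: 0.28}
      - {position: [-0.1732, -0.1732, 0.1732], charge: -0.125, lj_epsilon: 0.4, lj_sigma: 0.28}

# Default run protocol for the toy pipeline (desk-scale).
protocol:
  temperature: 300.0
  friction: 1.0
  dt: 0.002
  sample_stride: 10
  burn_in_steps: 1000

free_sim:
  site: f85_like
  water: toy_water
  ion: toy_fluoride
  replicas: 4
  n_steps: 50000          # 100 ps per replica
  persistence_ps: 5.0

relative:
  species_a: toy_fluoride  # lambda = 0: ion bound / 1: water bound
  species_b: toy_water
  site: f85_like
  bulk: bulk_shell
  n_windows: 9
  n_steps: 6000

absolute:
  species: [toy_water]
  site: f85_like
  bulk: bulk_shell
  restraint_k: 200.0
  n_windows: 9
  n_steps: 6000

thresholds:
  ddg_robust: 20.0
  dg_plausible: 5.0
  tau_ratio: 10.0
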