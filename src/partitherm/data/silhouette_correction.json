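{
 "version": 1,
 "description": "8th-order polynomial in normalised zenith (z/90), highest degree first, fitted to the ratio of the empirical standing-human projected area to the geometric whole-body silhouette of the default body at 91 integer zenith angles.",
 "default_body": {
  "mass_kg": 70.0,
  "height_m": 1.75,
  "area_m2": 1.843828916838765
 },
 "coefficients": [
  -32.6138425897431,
  147.73844654022113,
  -282.43088591268224,
  297.71508585613356,
  -190.5013577944613,
  77.48487738310408,
  -20.791629558330047,
  3.9455524159787605,
  0.38503224726843305
 ]
}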