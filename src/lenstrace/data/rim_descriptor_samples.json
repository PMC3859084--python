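{
  "comment": "Reference Fourier descriptors of three manually traced left eyeglasses rims, one per shape class: 14 complex (re, im) pairs per shape. The pair list carries no frequency labels of its own; the 'indices' field is this package's documented assumption that pairs run from highest to lowest frequency (canonical truncation order reversed), so the large-magnitude final pair is c(0) and the 12th pair the dominant first harmonic. These samples serve as serialization, round-trip and flip test fixtures, not as morphable database members and not for bit-exact shape claims: their high-frequency energy makes them self-intersect when reconstructed under this package's conventions.",
  "indices": [7, -6, 6, -5, 5, -4, 4, -3, 3, -2, 2, -1, 1, 0],
  "samples": [
    {
      "id": "sample_rectangular",
      "class": "rectangular_symmetric",
      "pairs": [
        [4430, -454], [-57.3, -379], [1110, -40.5], [-151, -416],
        [37.1, 303], [-88.4, -176], [-352, 255], [-566, -283],
        [-119, 281], [710, -375], [-29.4, 483], [5040, 35.8],
        [334, 258], [24700, 605]
      ]
    },
    {
      "id": "sample_elliptic",
      "class": "elliptic_symmetric",
      "pairs": [
        [874, 479], [185, -162], [684, 292], [18.5, 60.8],
        [185, 156], [-121, -223], [-28.6, -211], [-381, 214],
        [-119, 339], [-638, 308], [-12.7, 549], [1650, 168],
        [285, -271], [23200, -396]
      ]
    },
    {
      "id": "sample_asymmetric",
      "class": "asymmetric",
      "pairs": [
        [1750, -119], [-68.3, -526], [403, 136], [-142, -102],
        [217, 96.8], [-94.4, 2.60], [26.7, -71.9], [-554, -226],
        [-275, 203], [-289, -189], [-276, 358], [3000, 77.4],
        [377, 108], [25400, 813]
      ]
    }
  ]
}
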