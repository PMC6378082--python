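{
  "units": "mm",
  "segments": [
    {
      "name": "GMed_anterior",
      "group": "GMed",
      "section": "anterior",
      "cranial": [
        11.471528727020932,
        106.48976575756893,
        15.0
      ],
      "caudal": [
        1.818086391276367,
        -33.12458050322606,
        0.0
      ]
    },
    {
      "name": "GMed_middle",
      "group": "GMed",
      "section": "middle",
      "cranial": [
        -36.34026985042873,
        99.84407083094055,
        35.0
      ],
      "caudal": [
        -62.604989411610035,
        160.96446159058274,
        0.0
      ]
    },
    {
      "name": "GMed_posterior",
      "group": "GMed",
      "section": "posterior",
      "cranial": [
        -59.01689101245299,
        103.96336859327681,
        15.0
      ],
      "caudal": [
        -38.2744918526535,
        -34.66324104544031,
        0.0
      ]
    },
    {
      "name": "GMax_anterior",
      "group": "GMax",
      "section": "anterior",
      "cranial": [
        -71.54670399930751,
        114.33539473864965,
        25.0
      ],
      "caudal": [
        -20.987869384068908,
        -49.35802994642359,
        0.0
      ]
    },
    {
      "name": "GMax_middle",
      "group": "GMax",
      "section": "middle",
      "cranial": [
        -83.8779294019885,
        112.03427649246592,
        25.0
      ],
      "caudal": [
        -17.564524950111796,
        -53.964306033102595,
        0.0
      ]
    },
    {
      "name": "GMax_posterior",
      "group": "GMax",
      "section": "posterior",
      "cranial": [
        -95.1863143060968,
        108.69297274268382,
        25.0
      ],
      "caudal": [
        -26.376853837464164,
        -59.81928723647756,
        0.0
      ]
    },
    {
      "name": "TFL",
      "group": "TFL",
      "section": "whole",
      "cranial": [
        17.950770683750797,
        94.55083711895287,
        20.0
      ],
      "caudal": [
        -46.94783872693232,
        -63.86314250757831,
        0.0
      ]
    },
    {
      "name": "P",
      "group": "P",
      "section": "whole",
      "cranial": [
        -89.50225357665163,
        60.58250514204581,
        30.0
      ],
      "caudal": [
        40.30999314556497,
        -17.08853225223089,
        0.0
      ]
    }
  ]
}
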