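{
 "type": "FeatureCollection",
 "description": "Simplified lon/lat box approximations of Southern Ocean management areas (synthetic stand-ins for the official boundary shapefiles). Boxes are half-open: south/west edges inclusive, north/east exclusive.",
 "features": [
  {
   "type": "Feature",
   "properties": {
    "name": "58.5.1 Kerguelen",
    "category": "CCAMLR"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       63,
       -53
      ],
      [
       82,
       -53
      ],
      [
       82,
       -45
      ],
      [
       63,
       -45
      ],
      [
       63,
       -53
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "58.4.3b Banzare",
    "category": "CCAMLR"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       60,
       -62
      ],
      [
       80,
       -62
      ],
      [
       80,
       -53
      ],
      [
       60,
       -53
      ],
      [
       60,
       -62
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "58.4.1 East Antarctic",
    "category": "CCAMLR"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       80,
       -70
      ],
      [
       150,
       -70
      ],
      [
       150,
       -55
      ],
      [
       80,
       -55
      ],
      [
       80,
       -70
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "58.4.2 Prydz Bay",
    "category": "CCAMLR"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       30,
       -70
      ],
      [
       80,
       -70
      ],
      [
       80,
       -62
      ],
      [
       30,
       -62
      ],
      [
       30,
       -70
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "Drygalski MPA",
    "category": "MPA"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       63,
       -67
      ],
      [
       88,
       -67
      ],
      [
       88,
       -60
      ],
      [
       63,
       -60
      ],
      [
       63,
       -67
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "IWC Area III",
    "category": "IWC"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       0,
       -90
      ],
      [
       70,
       -90
      ],
      [
       70,
       0
      ],
      [
       0,
       0
      ],
      [
       0,
       -90
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "IWC Area IV",
    "category": "IWC"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       70,
       -90
      ],
      [
       130,
       -90
      ],
      [
       130,
       0
      ],
      [
       70,
       0
      ],
      [
       70,
       -90
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "IWC Area V",
    "category": "IWC"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       130,
       -90
      ],
      [
       170,
       -90
      ],
      [
       170,
       0
      ],
      [
       130,
       0
      ],
      [
       130,
       -90
      ]
     ]
    ]
   }
  }
 ]
}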