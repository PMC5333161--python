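{
 "edges": [
  {
   "genes": [
    "G000"
   ],
   "id": "e0",
   "reversible": false,
   "source": "M000",
   "target": "M001"
  },
  {
   "genes": [
    "G001"
   ],
   "id": "e1",
   "reversible": false,
   "source": "M001",
   "target": "M002"
  },
  {
   "genes": [
    "G002"
   ],
   "id": "e2",
   "reversible": false,
   "source": "M002",
   "target": "M003"
  },
  {
   "genes": [
    "G003"
   ],
   "id": "e3",
   "reversible": false,
   "source": "M003",
   "target": "M004"
  },
  {
   "genes": [
    "G004"
   ],
   "id": "e4",
   "reversible": false,
   "source": "M004",
   "target": "M005"
  }
 ],
 "name": "synthetic_demo",
 "nodes": [
  {
   "compound_ids": [],
   "id": "M000",
   "label": "M000",
   "x": 40.0,
   "y": 80.0
  },
  {
   "compound_ids": [],
   "id": "M001",
   "label": "M001",
   "x": 100.0,
   "y": 80.0
  },
  {
   "compound_ids": [],
   "id": "M002",
   "label": "M002",
   "x": 160.0,
   "y": 80.0
  },
  {
   "compound_ids": [],
   "id": "M003",
   "label": "M003",
   "x": 220.0,
   "y": 80.0
  },
  {
   "compound_ids": [],
   "id": "M004",
   "label": "M004",
   "x": 280.0,
   "y": 80.0
  },
  {
   "compound_ids": [],
   "id": "M005",
   "label": "M005",
   "x": 340.0,
   "y": 80.0
  }
 ]
}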