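{
 "circuits": [
  {
   "id": 1,
   "electrodes": {
    "1": 1,
    "2": 2,
    "3": 3,
    "4": 4
   }
  },
  {
   "id": 2,
   "electrodes": {
    "1": 5,
    "2": 6,
    "3": 7,
    "4": 8
   }
  },
  {
   "id": 3,
   "electrodes": {
    "1": 9,
    "2": 10,
    "3": 11,
    "4": 12
   }
  },
  {
   "id": 4,
   "electrodes": {
    "1": 13,
    "2": 14,
    "3": 15,
    "4": 16
   }
  },
  {
   "id": 5,
   "electrodes": {
    "1": 17,
    "2": 18,
    "3": 19,
    "4": 20
   }
  },
  {
   "id": 6,
   "electrodes": {
    "1": 21,
    "2": 22,
    "3": 23,
    "4": 24
   }
  },
  {
   "id": 7,
   "electrodes": {
    "1": 25,
    "2": 26,
    "3": 27,
    "4": 28
   }
  },
  {
   "id": 8,
   "electrodes": {
    "1": 29,
    "2": 30,
    "3": 31,
    "4": 32
   }
  },
  {
   "id": 9,
   "electrodes": {
    "1": 33,
    "2": 34,
    "3": 35,
    "4": 36
   }
  },
  {
   "id": 10,
   "electrodes": {
    "1": 37,
    "2": 38,
    "3": 39,
    "4": 40
   }
  },
  {
   "id": 11,
   "electrodes": {
    "1": 41,
    "2": 42,
    "3": 43,
    "4": 44
   }
  },
  {
   "id": 12,
   "electrodes": {
    "1": 45,
    "2": 46,
    "3": 47,
    "4": 48
   }
  },
  {
   "id": 13,
   "electrodes": {
    "1": 49,
    "2": 50,
    "3": 51,
    "4": 52
   }
  },
  {
   "id": 14,
   "electrodes": {
    "1": 53,
    "2": 54,
    "3": 55,
    "4": 56
   }
  },
  {
   "id": 15,
   "electrodes": {
    "1": 57,
    "2": 58,
    "3": 59,
    "4": 60
   }
  }
 ]
}
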